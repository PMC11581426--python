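# smx — single-molecule analysis of protein supercomplexes

`smx` is a Python toolkit for quantifying the composition and turnover of
multi-protein assemblies ("supercomplexes") imaged one at a time — for
example, postsynaptic scaffold-protein complexes extracted from brain
tissue, immobilized on a coverslip and imaged by TIRF microscopy, PALM, or
MINFLUX.  It is aimed at single-molecule biophysicists who have camera
movies or localization tables and want per-complex answers: *how many
tagged proteins does each assembly carry, how far apart are they, and how
fast are the subunits replaced?*

The package covers five analysis stages plus a seeded synthetic-data
generator that plants known ground truth for every stage, so the whole
pipeline is testable without any raw imaging data:

1. **Spot detection and trace extraction** (`smx.detect`) — local maxima by
   topographic prominence (ImageJ *Find Maxima* semantics), then per-spot
   intensity traces across the movie.
2. **Photobleaching step counting** (`smx.steps`) — Chung–Kennedy
   edge-preserving filtering, candidate steps from peaks of the filtered
   trace differential, and validation by a t-statistic (step height over
   the local regional variance).  The number of irreversible intensity
   drops per spot estimates the number of tagged proteins in that complex.
3. **SMLM clustering** (`smx.palm`) — merge repeated blinks of one
   fluorophore into objects (greedy, precision-sorted, run to a fixpoint),
   group objects within 160 nm into clusters by single linkage, count
   stoichiometries, measure dimer separations, and estimate image
   resolution by Fourier ring correlation (1/7 threshold).
4. **Class averaging of dimers** (`smx.classavg`) — align every
   two-protein cluster to a common frame (midpoint at origin, axis along
   x), sum unit-mass Gaussians of width = localization precision, and read
   the dominant intramolecular separation off the averaged profile with
   sub-grid quadratic refinement.
5. **Two-color coincidence and turnover statistics** (`smx.coincidence`,
   `smx.stats`) — match spots across channels at a strict <2 px offset
   (greedy nearest-first, one-to-one), classify complexes into old-only /
   new-only / mixed populations for pulse-chase experiments, Monte-Carlo
   chance-coincidence correction, and regional comparisons (one-way ANOVA,
   post hoc t-tests, Pearson correlation against protein half-life).

## The quantities at the core

For a trace $I_t$, the Chung–Kennedy filter output is
$\hat I_t = w_b \bar I_{[t-W,t)} + w_f \bar I_{[t,t+W)}$ with weights
$w \propto \mathrm{Var}^{-1}$ of each shuttling window ($W = 12$ frames by
default), so edges stay sharp while noise averages out.  A candidate step
at frame $c$ is validated by $t = |\Delta| / s^2_{\mathrm{pooled}}$, where
$\Delta$ is the difference of flanking raw-segment means and
$s^2_{\mathrm{pooled}}$ the pooled variance of the filtered flanks;
candidates with $t \ge 0.1$ are kept (peak threshold 75 counts, t-threshold
0.1 by default, both instrument-scale dependent).

For localization tables $(x, y, \sigma)$, objects closer than 160 nm form
clusters; a cluster with two members is a dimer, and the class average is
$\rho(\mathbf{r}) = \sum_i \mathcal{N}(\mathbf{r}; \mathbf{p}_i,
\sigma_i^2 I)$ over all aligned members.  Two-channel spots $a, b$ are
coincident when $\lVert a - b \rVert < 2$ px; populations are
$(n_A - n_c,\; n_B - n_c,\; n_c)$ over $n_A + n_B - n_c$ complexes.

## Worked example

`examples/01_photobleaching_step_counting.py` plants 5000 bleaching traces
whose stoichiometry follows a 63/24/13% (one/two/more) mixture, then counts
steps blind:

```
traces analyzed: 5000
recovered counts  1: 3168  2: 1222  >2: 610
planted counts    1: 3168  2: 1222  >2: 610
mean steps per trace with >=1 step: 1.49
```

At a signal-to-noise ratio of 20 the filter + t-statistic pipeline recovers
every planted stoichiometry bin exactly; the mean of ~1.5 steps per active
trace is the average tagged-protein copy number per complex.  The other
examples walk through PALM clustering (`02`), dimer class averaging
(`03`, recovering a planted 12.7 nm separation to 12.50 nm — the 0.2 nm
inward bias is the analytic mode shift of two overlapping Gaussians),
two-color turnover classification (`04`), regional statistics (`05`), and
the raw-movie path through spot detection (`06`).

A thin CLI mirrors the same stages for shell use:

```bash
smx simulate traces --n 100 --out traces.csv
smx steps --traces traces.csv --out steps.csv
smx cluster --locs locs.csv --radius 160 --out clusters.csv
smx coincide --a spots_a.csv --b spots_b.csv --offset 2 --out coinc.json
```

## Data formats

* Localization tables: CSV with header `x_nm,y_nm,frame,precision_nm`
  (one row per blink, the output of standard SMLM fitting software).
* Spot lists: CSV `x_px,y_px,channel` (integer pixels).
* Movies: 16-bit unsigned multi-page TIFF.
* Reports: JSON; ground truth as sidecar JSON/CSV next to the table.

## Scope

The package consumes localization tables rather than fitting PSFs (use
your fitting software of choice upstream), assumes drift-corrected,
channel-registered inputs, and models 2-D fields.  See `docs/methods.md`
for the full model description, parameter defaults, and limitations.
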