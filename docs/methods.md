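# Methods

## The estimation problem

Alchemical free-energy calculations measure *differences*: the relative
binding free energy (RBFE) of two ligands on one receptor, the receptor
hopping free energy (RHFE) of one ligand moved between two receptors — a
direct estimate of its binding selectivity free energy (BSFE) — and the
receptor swapping free energy (RSFE) of two ligands exchanged across two
receptors. Writing ΔG°b(RL) for the standard binding free energy of complex
RL, the identities are

    ΔG_r(R; L1→L2)      = ΔG°b(R L2) − ΔG°b(R L1)
    ΔG_h(L; RA→RB)      = ΔG°b(RB L) − ΔG°b(RA L)          (= BSFE)
    ΔG_s(RA L1, RB L2)  = ΔG_r(RA; L1→L2) − ΔG_r(RB; L1→L2)
                        = ΔG_h(L1; RA→RB) − ΔG_h(L2; RA→RB)

with the selectivity coefficient s(L; RB over RA) = exp(−ΔG_h/kBT) and the
per-pair ratio s(L1; RA over RB)/s(L2; RA over RB) = exp(+ΔG_s/kBT).

Given a set of such difference measurements d_e with standard deviations
σ_e over a graph of nodes x (either receptor–ligand complexes or per-ligand
BSFEs), plus at least one anchored reference value per connected component,
the maximum-likelihood estimates under independent Gaussian errors minimize

    F(x) = Σ_e (x_head − x_tail − d_e)² / σ_e².

This is a weighted least-squares problem on the graph; `selectnet.diffnet`
solves the reduced weighted-Laplacian normal equations L x = b over the
non-anchored nodes with a symmetric positive-definite (Cholesky)
factorization, and takes node variances from the diagonal of L⁻¹. The same
solver serves both network modes; only the meaning of the nodes differs.

## Conventions and parameters

* **Units.** All free energies in kcal/mol; kB = 0.0019872041 kcal/(mol·K).
* **Temperature.** Default 300 K (the simulation temperature of the source
  calculations). Experimental pKi conversions commonly use 298.15 K, so
  temperature is a `ThermoContext` parameter rather than a constant.
* **Uncertainty convention.** Reported uncertainties are *twice* the
  standard deviation throughout, matching the source tables. Quadrature
  propagation is scale-invariant so sums/differences are propagated directly
  on the 2σ scale; the solver divides by two to form σ_e. A global rescaling
  of all variances cannot move the minimizer, so central estimates are
  insensitive to this convention — only reported uncertainties depend on it.
  Missing uncertainties (typical for experimental values) propagate as
  absent, never as zero.
* **Edge orientation.** Every edge is directed with value = x(head) −
  x(tail), and the file formats state both endpoints explicitly; no signs
  are inferred. A swap row lists (ligand_a at receptor_a, ligand_b at
  receptor_b) and constrains BSFE(ligand_a) − BSFE(ligand_b) for the hop
  receptor_a → receptor_b. This matches the published tables: the (G1, G2p)
  swap value +1.27 sits against BSFE(G1) − BSFE(G2p) = +1.53 from the
  direct hops.
* **Anchors.** Hard by default: anchored nodes are eliminated from the
  linear system and reproduce their reference values exactly, matching the
  published "single reference complex" analyses. A soft-anchor mode
  (anchors as Gaussian prior terms weighted by their own reported
  uncertainty; σ = 10⁻⁶ kcal/mol when none is given) is available behind a
  flag for fusing several absolute references.
* **Significance testing.** Direct-vs-indirect discrepancies are tested
  with a two-sided z test (normal tail), the large-sample limit of a t test
  appropriate when σ estimates come from long time series; α defaults to
  0.05. No multiple-testing correction is applied across edges.
  Comparisons between quantities that share inputs (e.g. two ABFE-derived
  differences involving a common complex) ignore the induced covariance;
  this matches how published quadrature columns are formed and slightly
  overstates the combined σ in those cases.
* **RMSD aggregation.** Network-vs-direct RMSDs are computed over
  non-reference nodes only: the reference deviation is identically zero and
  would dilute the statistic.
* **Hysteresis.** A swap computed forward and in reverse forms a closed
  cycle, so the deviation is |forward + reverse| with quadrature error.

## Numerical choices

* Solvability is decided structurally (every connected component of the
  undirected edge graph must contain an anchor) *before* factorization;
  there is no pseudo-inverse fallback, so an under-determined network fails
  loudly instead of returning a silently gauge-fixed answer.
* Zero-uncertainty edges are rejected as degenerate weights; exact
  constraints belong in anchors.
* The condition number of the reduced system is computed on every solve and
  logged; above 10¹² a RuntimeWarning is emitted.
* Display rounding (reports, CLI tables) is half-to-even at 0.01 kcal/mol,
  the precision of the published tables; stored values keep full precision.

## Fixture regression tolerances

The packaged fixtures transcribe the published measured columns for the
two-host (TEMOA/TEETOA, guests G1–G5) and trypsin/thrombin
(benzamidine/1-amidinopiperidine) systems. Derived single-step quantities
are checked at printed precision (±0.005 kcal/mol). Network solutions are
checked at ±0.05 kcal/mol: the published values are printed at 0.01
precision but were produced by an implementation whose internal conventions
(σ vs 2σ weighting, uncertainty estimator) are not fully specified. In
practice our estimates agree with the printed central values to ≤0.01
kcal/mol, and our 2σ uncertainties fall in the same 0.1–0.2 kcal/mol band
as the printed ones; the printed ± values are treated as indicative, not as
regression targets. Two documented data discrepancies are inherited from
the sources: the experimental thrombin relative affinity (0.41) and the
quoted benzamidine selectivity coefficient (9.7) are not reproducible from
the printed pKi values (they presumably used unrounded Ki data; the trypsin
entry, 1.46 kcal/mol from ΔpKi = 1.07 at 298.15 K, does reproduce), and the
running-text forward/reverse swap pair (2.05, −2.32; deviation 0.27) differs
from the tabulated one (2.37, −2.88; deviation 0.51). Both pairs ship; the
0.27 deviation belongs to the text pair.

## The synthetic generator

`selectnet.synthetic` draws a ground-truth ABFE table uniformly over a
value range (default −12 to 0 kcal/mol, the span of typical host–guest and
fragment affinities), derives all difference quantities from it exactly,
and emits networks whose edges are true differences plus independent
N(0, σ²) noise, with reported uncertainty 2σ. Defaults — two receptors,
five ligands, all-pairs relative edges, one hop edge, σ = 0.2 kcal/mol
(≈ the 0.12–0.17 kcal/mol 1σ of the fixture calculations, rounded up) —
mirror the fixture study's shape. When σ = 0 a nominal tiny uncertainty
(10⁻⁶) is recorded so the network remains weightable; consistent data make
the solution weight-independent, so noiseless recovery is exact.

What the generator deliberately does **not** emulate: correlated errors
between edges sharing a simulation leg, force-field bias (noise is centered
by construction), anharmonic/slow-convergence error distributions, and
hysteresis. Passing recovery tests therefore demonstrate that the estimator
is correct and calibrated *under its own error model* — unbiased (Monte
Carlo |bias| < 0.02 at σ = 0.2 over 200 replicates) with ≈95% empirical 2σ
coverage — not that real alchemical data satisfy that model; the
consistency diagnostics exist precisely to probe the latter.

Replicate r of an experiment reseeds the generator deterministically from
(seed, r), so every experiment is reproducible from its parameters alone.
Monte-Carlo test sizes (200 replicates of the 2×5 all-pairs network,
≈1800 node-replicates) keep the full suite under a few seconds while
leaving the 93–97% coverage band and the 0.02 bias bound comfortably
outside Monte-Carlo noise (SEM ≈ 0.004 kcal/mol).

## Known limitations

* One ordered receptor pair per selectivity network; multi-receptor
  selectivity requires solving in complex mode with hop edges.
* No experiment-design facilities (edge selection / variance allocation).
* The error model is independent Gaussian per edge; correlated-error or
  Bayesian treatments are out of scope.
* No chemistry awareness: node identifiers are opaque case-sensitive
  strings, and no structure formats are read.
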