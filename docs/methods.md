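# Methods

## Scope and model

`h3csp` quantifies how the backbone chemical shifts of the histone H3 core
domain differ between experimental conditions — in the motivating system,
16-mer nucleosome arrays whose linker DNA is 15, 30 or 60 bp long. Chemical
shifts are exquisitely sensitive reporters of local conformation, so a
per-residue comparison of two conditions localizes where the protein
environment changes without requiring a structure of either state.

For each residue with amide ¹H (H^N), ¹⁵N and ¹³Cα shifts available in both
conditions, the pipeline computes the weighted combined difference

    Δδ = sqrt( Δδ_HN² + α·Δδ_N² + β·Δδ_Cα² )

with β = 0.3 and α = 0.14 for all residue types except glycine, where
α = 0.2. The weights rescale the heavy-atom differences to the smaller
dispersion of the amide-proton axis, so each nucleus contributes comparably;
the glycine-specific α reflects the wider ¹⁵N dispersion of glycines.
Differences are taken as (condition A − condition B) per nucleus; Δδ is
invariant to the order of the pair and to the sign of any input.

Partial data are handled conservatively: a residue missing any of the three
nuclei in either condition keeps whatever per-nucleus differences exist but
gets no combined value and is excluded from all combined summaries (prolines,
lacking the amide, are therefore always "incomplete"). The per-nucleus
summary `mean_abs_nucleus_diff` uses all residues carrying that nucleus in
both conditions, independent of completeness elsewhere; this choice is
recorded in output metadata.

## Significance thresholds

Thresholds are derived from the Δδ profile itself rather than fixed a
priori. The background subset is the complete records with Δδ strictly below
a trim cutoff (default 0.1 ppm, single pass); significance levels are
`mean + k·SD` of that subset for k = 2.5 and 5. Residues are classified with
thresholds as category floors (lower bound inclusive): `below`,
`significant` (≥ lower), `pronounced` (≥ upper); records without a combined
value are `incomplete`. Tie handling at a threshold is not standardized in
the field, so the inclusive-floor convention is documented here and applied
deterministically.

Choices that were genuinely open, and what was decided:

* **Single-pass trim** at the fixed cutoff is the default; the iterative
  re-trimming variant common in solution-state CSP work (discard values more
  than `iter_k` = 3 SD above the subset mean until stable) is available via
  `iterative=True` but off by default.
* **Sample SD** (n−1 denominator) everywhere a spread is reported; a
  population-SD option exists (`ddof=0`). For a single observation the
  sample SD is undefined and is reported as NaN.
* **Per-comparison thresholds** are the default; `derive_thresholds` accepts
  a list of profiles to pool the background subset across comparisons when a
  common scale is wanted.
* **Absolute fallback levels** (0.10 and 0.15 ppm) are available via
  `absolute_thresholds` for cross-dataset comparability.
* At least 3 background residues are required; fewer raises an error
  suggesting a larger cutoff rather than silently producing a degenerate SD.

## Assignment completeness and intensities

Completeness accounting runs over an inclusive residue range (default
44–132, the detectable H3 core). Prolines are excluded from numerator and
denominator — the fingerprint experiments are amide-detected, so prolines
can never appear. A residue counts as assigned when its H^N and ¹⁵N shifts
are both present (configurable to also require Cα). On the embedded H3
sequence this yields 87 assignable residues in 44–132 (prolines 66 and 121
excluded) and, with the L1-loop residues 78–81 missing, 83 assigned.

Peak intensities are normalized to the dataset maximum (anchor = 1 exactly);
a mean-anchored variant is accepted but re-anchored to the maximum so
profiles are mutually comparable. Profile similarity is summarized as RMSD
and Pearson r over shared residues (≥ 3 required).

## Structure mapping

Per-residue values (combined Δδ, or category codes 0–3 for
incomplete/below/significant/pronounced) are written into the B-factor
column of a PDB file for coloring in molecular viewers. Matching is by
author residue number on the selected chains; both H3 copies of an octamer
receive identical values since the NMR data do not distinguish them. Only
columns 61–66 of ATOM/HETATM records on selected chains are rewritten — the
rest of the file is preserved byte for byte. Values outside the fixed-column
range (−99.99 to 999.99) are clipped with a logged warning. Insertion codes
are unsupported (the H3 chains of nucleosome structures have none).

## Synthetic data generator

The generator emulates the *structure* of backbone shift depositions for the
H3 core, not their physics:

* **Baselines**: an embedded per-residue-type random-coil table (values near
  the standard literature random-coil shifts) plus fixed helix offsets
  (Cα +2.8, CO +1.8, H^N −0.25, N −1.5, Cβ −0.5 ppm) inside the four core
  helices. Absolute baselines are immaterial downstream — every statistic
  uses differences only.
* **Perturbations**: each condition plants (ΔH, ΔN, ΔCα) triples at
  designated interface residues. The default three-condition spec mimics the
  linker-length series: "60bp" unperturbed, "30bp" with 4 moderately
  perturbed sites, "15bp" with 8 more strongly perturbed sites; every
  planted triple has combined Δδ ≥ 0.15 ppm.
* **Noise**: independent Gaussian per nucleus, defaults 0.01 ppm (¹H) and
  0.05 ppm (heavy nuclei) — chosen so the background Δδ between two noisy
  conditions averages ≈ 0.05 ppm, the regime reported for real arrays, and
  so that the derived thresholds land near 0.10/0.15 ppm.
* **Missingness**: residues outside 44–132 and in the undetectable segments
  (35–43, 78–81) are removed; prolines lack amide shifts; glycines lack Cβ.
* **Seeding**: one master seed; per-condition streams derived via
  `numpy.random.SeedSequence.spawn`, so runs are byte-reproducible.

What the generator does **not** emulate: line broadening and linewidth
variation, intermediate-exchange signal loss as a continuous intensity
model (intensity attenuation is a simple multiplicative factor), referencing
offsets between depositions (an explicit per-nucleus offset can be applied
on read instead), and any physical relationship between linker length and
perturbation magnitude. Passing recovery tests therefore demonstrates that
the statistical machinery is correct under the stated noise model, not that
real arrays behave this way.

## Verification strategy

* The combined-Δδ engine is checked against an independently coded direct
  evaluation on 1,000 random inputs at 1e-12 relative tolerance, plus
  property tests (sign-flip invariance, positive scaling, monotonicity in
  each nucleus, per-term lower bounds).
* The threshold procedure is pinned to a hand-computable example:
  Δδ = {0.02, 0.04, 0.06, 0.30} with cutoff 0.1 and k = 2.5/5 gives subset
  mean 0.04, SD 0.02, thresholds exactly 0.09 and 0.14 ppm.
* End-to-end recovery: over 200 seeded replicates of the default generator,
  classification flags planted sites with sensitivity ≥ 0.95 at a
  false-positive rate ≤ 0.05. The replicate count keeps the whole suite in
  the tens of seconds on one core.
* Round-trip identity of both I/O dialects (including a Hypothesis property
  over random tables) and byte-stability of seeded simulation are asserted
  on every build.

## Problem sizes

Default analyses operate on the 135-residue H3 sequence with 89 detectable
core positions and three conditions (418 shifts per condition); recovery
statistics use 200 replicates × 2 comparisons. All analysis scripts complete
in seconds.

## Known limitations

* The NMR-STAR reader handles the flat assigned-chemical-shift loop of
  backbone depositions; it ignores ambiguity codes and does not implement
  the full STAR grammar (nested frames, multiline values).
* The significance procedure is an SD heuristic, not a hypothesis test; no
  multiple-testing correction is applied or implied.
* mmCIF coordinates are not written; PDB fixed-column only.
* Sequences with author numbering gaps are represented with `X` placeholders;
  residue-type validation is skipped at such positions.
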