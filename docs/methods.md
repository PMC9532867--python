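# Methods

## Scope and model

`sspmine` implements a genome-mining analysis for plant small secreted
peptides (SSPs). The underlying biological model is the canonical SSP
precursor: an N-terminal signal peptide that routes the protein into the
secretory pathway, a variable middle region, and a conserved C-terminal
domain that is proteolytically released as the active mature peptide.
Mining therefore proceeds by elimination (the secretion funnel) followed by
recognition (family motifs), and finally by expression screening under
abiotic stress. The package computes; it does not model uncertainty — every
stage is a deterministic rule, which is what makes it fully testable
against planted ground truth.

## The secretion funnel

Stages run in a fixed order; a record is rejected at the first failing
stage and later stages are not evaluated. Survivor counts after each stage
are the funnel's primary output.

1. **Length.** Precursors of more than `max_length` residues (default 250,
   inclusive bound) are removed. One representative transcript per gene is
   used: the longest, ties broken to the lexicographically smallest
   transcript id.
2. **Signal peptide.** Two interchangeable sources. The *built-in*
   heuristic is a classical n/h/c-region rule: within the first
   `sp_search_limit` (40) residues there must be an 8-residue window
   starting at positions 3–25 with at least 6 residues from {A,I,L,M,F,V,W}
   (the hydrophobic h-region), and a cleavage position *p* in 15–35, at
   least two residues past the end of such a window, with residues at *p*
   and *p*−2 from {A,G,S,C,T,V} (the (−3,−1) small-residue rule). The
   smallest qualifying *p* is the cleavage site; the score is the
   hydrophobic count of the strongest licensing h-window divided by 8.
   Sequences under 15 residues are a *no-call error*, distinct from a
   negative call. The *external* source is a tab-separated adapter for a
   predictor's short-format output (`id`, label, `CS pos: n-n+1`); missing
   ids are a hard error by default (silent coverage gaps would corrupt the
   funnel counts), optionally treated as negatives.
3. **Transmembrane.** Run on the mature (signal-peptide-removed) sequence.
   Built-in: Kyte–Doolittle hydropathy, sliding window of
   `hydropathy_window` (19) residues; the maximal-mean window (leftmost on
   ties) calls a transmembrane segment when its mean exceeds
   `hydropathy_cutoff` (1.6). Unknown residues (X, \*) score 0. Sequences
   shorter than the window are negative. An external adapter accepts
   `id`/TM-count tables.
4. **ER retention.** The full precursor's final four residues are compared
   (case-insensitively) with `kdel_motifs` (default {KDEL, HDEL}); a match
   marks an ER-docked protein, which is not secreted. The check uses the
   precursor C-terminus because the motif is C-terminal regardless of where
   cleavage occurred.
5. **Truncation.** A sequence is truncated when it contains an internal
   stop `*`, lacks the initiator methionine, or contains any ambiguous `X`.
   This is a package definition: annotation pipelines flag truncation in
   different ways, and this conservative sequence-level rule is the version
   that can be tested. It may differ from a given genome project's own
   annotation flags.

The built-in predictors are deliberately simple deterministic stand-ins for
the neural/HMM tools normally used in such surveys. The funnel logic — not
the predictor — is the subject of this package; the adapters exist so that
genome-scale reruns can use any external predictor's output.

## Family registry and classification

The packaged registry (`src/sspmine/data/families.yaml`) lists 38 known
plant SSP families with peptide class (PTM, CRP, non-Cys/non-PTM,
functional precursor), description, mode of action (Signal, Antimicrobial,
PeptidaseInhibitor, Unknown; multi-valued), a reported wheat gene count per
family (total 1,790), and a motif. Registry arithmetic (class shares as
half-up-rounded integer percentages, per-mode aggregates) reproduces the
published per-class breakdown; the CRP share computes to 69 % from the
table's own numbers (1243/1790), one point off the loosely rounded 70 %
sometimes quoted alongside it, and the Signal-mode rows sum to 1,325 genes
in 24 families.

Most family motifs are **package conventions, not database
reconstructions**: the original survey classified candidates by homology
against an external peptide database whose profiles are not redistributable.
Five motifs encode genuinely described sub-structure — CEP and PIP carry the
shared `SGPS`/`GxGH` architecture, CLE ends in the activity-essential HN/H,
HEVEIN is an eight-cysteine chitin-binding skeleton, HAIRPININ a
four-cysteine hairpin — while the remaining 33 are synthetic consensus
sequences (14–16 residues, pairwise sliding identity < 0.5, even cysteine
counts for CRP-class families) that make the classification contract
testable end to end. The registry is an editable YAML file; swapping in
curated motifs or externally produced assignments changes nothing else.

Classification scores each motif over the C-terminal `cterm_window` (60)
residues of the mature sequence: consensus motifs by best sliding identity
against their `min_identity` threshold (default 0.75), regex motifs as
binary matches. The best score wins; ties break by registry order. A
precursor matching both CEP and PIP is resolved by the spacer rule — locate
the first `SGPS`, find the nearest following `GxGH`, and count the residues
strictly between: one → CEP (with a warning when it is not the canonical
proline), two → PIP, anything else neither — and is never reported as a
tie.

Cysteine profiling counts cysteines over the **entire** mature sequence
(not only the C-terminal window): an even count within [`cys_min`,
`cys_max`] (2–16) marks a CRP. The CRP spectrum reports the histogram over
CRPs and the share with at most 12 cysteines.

## Domain scanning and novel families

Tandem domains are found by greedy leftmost non-overlapping matching over
the whole mature sequence (multi-domain repeats live in the variable
region, so the scan is not restricted to the C-terminus); after each hit
the scan resumes `min_gap` (default 0) residues past the hit end. Greedy
matching is deterministic and oracle-checkable: concatenating *k* planted
domains with gaps ≥ `min_gap` yields exactly *k* hits, and overlapping
candidates resolve to the leftmost.

The DYY detector scans the C-terminal 40 residues for a 13-mer beginning
`DY`, scores identity to a packaged consensus (`DYYKPAGSNRPGH`), and
reports the best window at ≥ 0.5 identity. The CRP8CI detector requires
exactly eight cysteines in the C-terminal window and assigns one of three
groups by inter-cysteine spacing templates (per-gap tolerance ± 1 residue;
best total deviation wins, lowest group on ties). Both the DYY consensus
and the spacing templates are packaged defaults for families that were
described only graphically; they are user-overridable and the planted
synthetic members are generated from the same definitions, so recovery
tests exercise the mechanism, not the particular strings.

## Stress-expression calling

Inputs are a TPM matrix (genes × conditions) and a contrast design mapping
each stress condition to its control with a stress type and timepoint.
Thresholds: `tpm_meaningful` = 1 TPM, `fold_threshold` = 2. Branch order
matters and is fixed: control < 1 with stress ≥ 1 → *specifically
upregulated* (no ratio is reported; a ratio against sub-threshold
expression is not meaningful, and this also handles control = 0 without
division); otherwise both sides ≥ 1 and stress/control ≥ 2 → *upregulated*;
else not called. Requiring the stress side to also be meaningful on the
ratio path prevents 0.1 → 0.3 artifacts and follows directly from the
"meaningful TPM" rule.

A gene is *responsive under a stress type* when called (either category) in
at least one contrast of that type. Overlap regions over the power set of
types are exclusive, so they sum to the number of genes called anywhere;
deduplication sends genes responsive under exactly one type to that type's
exclusive set and the rest to a multi-stress set (the five sets partition
the responsive genes). Family summaries report member counts, responsive
fractions, and a flag requiring a strict majority of members responsive
within every stress type separately. No multiple-testing machinery is
involved anywhere — the procedure is pure thresholding, reproduced as such.

## Synthetic data: what it emulates and what it does not

The proteome generator builds each category so the funnel treats it as
designed: planted SSPs carry a constructed signal peptide (M-K n-region,
eight-residue hydrophobic core, non-small spacer, A-x-A cleavage site) that
the built-in heuristic recognises at exactly the intended cleavage site; a
hydrophilic variable region (alphabet without C, Y or hydrophobics, so no
spurious transmembrane windows, CRP counts or DY hits); and a family
consensus domain at the C-terminus. Decoys violate exactly one stage each:
a 21-leucine stretch (transmembrane), a K/HDEL tail (ER), an internal
stop/missing-M/X (truncation), excess length (size), and background
sequences drawn i.i.d. from plant-proteome-like residue frequencies and
resampled until the built-in heuristic reports no signal peptide
(non-secreted by construction — without the resampling step roughly a third
of random plant-composition N-termini satisfy the classical heuristic,
which would make the category labels false). Default mix: 50 planted, 10
TM, 5 K/HDEL, 5 truncated, 30 background (100 sequences). Because category
semantics hold exactly, per-stage survivor counts have a closed form and
built-in precision/recall on clean plants are 1.0; a `hard_mode_fraction`
weakens planted h-regions to 5/8 hydrophobics for threshold-sensitivity
studies. The generator does **not** emulate homology structure, isoform
complexity, hexaploid subgenome copies, or borderline signal peptides —
passing tests show the pipeline's rules are implemented correctly, not that
the built-in heuristics match neural predictors on real proteomes.

The expression generator mirrors a drought/heat/combined (1 h, 6 h) leaf
design and a salt (6/12/24/48 h) root design: 10 contrasts over 16
conditions with shared per-timepoint controls. Baselines are log-normal
(median 5 TPM, σ = 0.5); planted ratio-genes have baselines redrawn to
≥ 2 TPM so the planted category survives the caller's branch order even at
zero noise; planted switched-on ("specific") genes are built low everywhere
(0.1–0.5 TPM) except their planted stress cells (2–6 TPM), and after
multiplicative log-normal noise (default σ = 0.2) their planted
control/stress cells are clamped below/above the meaningful level so the
construction holds in every replicate. The default plan plants a 10-gene
core responsive to all three leaf stress types, per-type sets (40 drought,
30 heat, 20 combined, 60 salt) and specific sets (15 drought, 25 salt) in
a 1,000-gene matrix; remaining genes are nulls. Nulls can still produce
occasional false calls under noise (by design — the caller's false-positive
behaviour is part of what the tests observe); recovery of planted
upregulated genes at fold 4 and σ = 0.2 runs ≈ 0.99 over seeds.

## Numerical and design choices

- Positions are 1-based inclusive throughout (protein and genomic); motif
  and window internals use 0-based half-open slices.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical FASTA/TSV outputs on any platform (integer
  state, no locale dependence).
- Percent rounding is half-up to integers for registry shares.
- The chromosome-end summary counts a gene as terminal when its locus
  midpoint lies within `end_fraction` (0.2) of either end, boundary
  inclusive; a midpoint exactly at half the length is interior.
- Header parsing defaults to the Ensembl `gene.n` dialect; a `generic`
  dialect takes the whole first token as both gene and transcript id.
- The funnel's ER check and the length bound are inclusive comparisons;
  the transmembrane call is a strict inequality (mean > cutoff).
- `registry_summary` counts a multi-mode family's genes once per mode; the
  "one family per gene" rule applies to classification (best score), while
  multi-domain multiplicity is reported separately by the domain scanner.
- Run manifests record the config snapshot, input digests and per-stage
  counts; the timestamp is the only non-deterministic field, so determinism
  checks compare data artifacts bytewise and manifests structurally.

## Known limitations

- The built-in signal-peptide and transmembrane heuristics are classical
  rules, not trained models; on real proteomes they will disagree with
  modern predictors, which is why external-call adapters are first-class.
- 33 of the 38 family motifs are synthetic conventions; genome-scale
  classification of real data should replace them with curated profiles or
  external family calls via the adapter slot.
- The spacer rule anchors at the first `SGPS` occurrence in the C-terminal
  25 residues; nested repeats of the sub-motifs resolve to neither family.
- The expression caller implements thresholding only; it is not a
  differential-expression method and reports no significance measure.
- Truncation is defined at the sequence level and may not coincide with an
  annotation project's internal truncation flags.
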