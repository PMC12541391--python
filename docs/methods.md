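# Methods

This note describes the models, conventions and numerical choices behind
`editoform`, stage by stage, and what the synthetic-data generators do and
do not emulate.

## Editing sites and codon arithmetic

A C-to-U editing site is identified by the compact nomenclature
`<gene>eU<pos><refAA><editedAA>p<freq>`, e.g. `nad2eU821SFp100`: editing of
the *nad2* CDS at nucleotide position 821 changes a serine (unedited) to a
phenylalanine (edited), with a wild-type editing frequency of 100%.
Positions are 1-based within the coding sequence; this is the only
convention under which the printed amino-acid positions follow from the
nucleotide positions (821 → codon ⌈821/3⌉ = 274, 739 → 247, 299 → 100,
110 → 37, 26 → 9, 131 → 44). The codon offset is `((pos−1) mod 3) + 1`.

Although editing is C-to-U at the RNA level, the edited base is stored as
T because all sequence I/O is DNA-level FASTA. Validation checks that the
genomic base at the site is C and that the unedited and C→T-edited codons
translate (standard genetic code — plant mitochondria use it) to the two
amino acids named in the identifier. Silent sites (ref = edited amino
acid) are parsed and validated but excluded from proteoform enumeration by
default. The `pNN` token is the wild-type editing frequency; mutant
frequencies come from a separate table column. An edit that would create a
stop codon cannot be expressed in the identifier grammar (there is no
stop letter), so stop-creating variants can only arise from raw,
unvalidated site objects; enumeration drops them with a logged reason
rather than emitting truncated sequences.

## Proteoform enumeration

A proteoform is defined by a variant signature: each selected site is
either edited (`E`) or unedited (`U`). The default mode enumerates all
2^n signatures per gene (n = nonsilent sites), deduplicating sequences
that collide at the protein level (the fully edited signature is
enumerated first and wins ties). Genes considered here carry at most a
handful of affected sites, so full combinatorics are tractable; above a
cap (default 4096 signatures) the enumeration falls back to a per-site
mode (fully edited reference plus one single-site-unedited variant per
site), which is the minimal database that still distinguishes every site.
Whether a search database should use full combinatorics or per-site
variants is a user decision; both are provided.

FASTA headers follow `gene|accession|site=E,site=U,...`, so a header is a
complete, parseable description of the variant. No decoys or contaminants
are appended — that belongs to the search engine.

## In-silico digestion and masses

Digestion is fully tryptic with up to 2 missed cleavages; peptides are
kept if they span 7–50 residues and 500–5000 Da, matching the constraints
of the database searches the pipeline is designed around. Two cleavage
rules are explicit config: `trypsin_p` (cleave after K/R, including
before proline; the default) and `trypsin_strict` (no cleavage before
proline), because different search configurations use either. N-terminal
methionine is not clipped — the simplest reproducible choice.

Masses are monoisotopic: sum of residue masses (pyteomics values) plus
water (18.01056 Da) plus fixed-modification deltas, default
carbamidomethyl-cysteine (+57.02146 Da) reflecting the alkylation used in
sample preparation. Masses are compared with an absolute tolerance of
1e-3 Da. The theoretical peptide count used as the iBAQ denominator is
the number of fully tryptic, 0-missed-cleavage peptides in the length
window (the mass filter is not applied there).

## Editing-specific peptide pairs and evidence rules

For each site, the peptides of the edited and unedited proteoform that
cover the site's codon are paired by coordinates. When the substitution
creates or destroys a K/R cleavage point the coordinate sets differ; the
leftovers are matched by maximal overlap and flagged `cleavage_altering`
(the two forms are then not one-to-one and their mass difference is not
the residue delta). For ordinary pairs the mass delta equals the residue
mass difference of the substitution exactly. Pairs whose forms differ
only by isoleucine↔leucine are flagged `il_ambiguous` and rejected by
default: the two forms are isobaric and cannot be distinguished by MS.
(No C→U edit can interconvert I and L under the standard code, so this
flag matters only for user-supplied pairs.)

The PTM mass-mimicry screen flags any modification whose monoisotopic
delta lies within ±2 Da (inclusive) of the pair's mass delta and whose
site specificity is compatible with the *unedited* residue — a modified
unedited peptide is what could masquerade as the edited form. A bundled
table of 42 common modifications ships with the package
(`data/modifications.tsv`); it is deliberately minimal, avoids any network
dependency, and can be replaced by a fuller user-supplied TSV. Mimicry
hits are reported, not auto-rejecting, because resolving them requires
inspecting spectra; a strict mode rejects pairs with unresolved mimicry.

Evidence rules for accepting an editing-specific identification:

* **score** — at least one PSM at or above its score-scale threshold
  (Andromeda ≥ 100, Hyperscore ≥ 20; the two scales correspond to the two
  search engines whose outputs this pipeline consumes);
* **ion_coverage** — among the threshold-passing PSMs, at least one
  observed b- or y-ion whose residue span includes the edited position
  (b_i covers positions 1..i, y_j the last j residues). This is the
  literal "covered by a b- or y-ion" rule, not flanking-ion site
  localization; if no PSM passes the score rule, the coverage rule is
  evaluated over an empty set and also fails;
* **spectra_count** — at least 2 distinct MS/MS spectra in total (no
  "one-hit wonders");
* **mbr_only** — at least one identification not transferred by
  match-between-runs.

A pair is accepted when every observed form passes every rule; the
decision lists all failed rules. Evaluation is deterministic,
order-independent and idempotent.

The protein-level editing fraction is estimated as
edited/(edited+unedited) summed intensity — the protein-level analogue of
a transcript editing frequency. It is undefined (NaN, with a warning)
when both intensities are zero.

## Complexome profiles

Profiles are protein×fraction matrices (43 fractions by default). The
internal fraction axis runs top→bottom of the displayed gel (high
apparent mass first); lanes cut bottom-to-top are flipped at load with an
orientation flag, to avoid silent orientation bugs. Maps can be built at
protein level (iBAQ when theoretical peptide counts are supplied),
peptide-sum level, or individual-peptide level (for editing-specific pair
profiles).

Display normalization scales each profile to its maximum (100); all-zero
rows are dropped with a log entry. The operation is idempotent and
scale-invariant. Module profiles are elementwise sums of member rows
*before* display normalization, so partitioning modules conserve column
totals. Map comparison rescales the non-reference condition by a single
global factor equating total intensity over shared proteins — the
simplest scheme consistent with reference-based normalization; the exact
algorithm of interactive complexome viewers is unpublished, so the
strategy is a pluggable function boundary.

Fraction→mass calibration fits log10(mass) linearly against fraction
index from ≥2 markers (gradient-gel migration is approximately
log-linear in native mass); the fit must be monotone and reproduce every
marker within 5%. Peak calling uses local maxima with prominence ≥ 10% of
the profile maximum (scipy `find_peaks`; the profile is padded with its
minimum so edge maxima are detected), reported with apparent masses and
sorted by height. A bundled, editable table
(`data/complex1_modules.tsv`) encodes the conventional complex I assembly
scheme — N, Q, P_P, P_D modules and the kDa-named intermediates with
their Arabidopsis gene identifiers — as default data for module
aggregation on real inputs.

## Differential abundance

Protein groups are kept when quantified (>0) in ≥4 of the 6 samples *and*
in every replicate of at least one genotype; both thresholds are config.
Intensities are log2-transformed; missing values are drawn per sample
from Normal(mean − 1.8·sd, (0.3·sd)²) of that sample's observed log2
values. The downshift/width pair is the de-facto standard for this
left-censored-missingness workflow and is exposed as config; the
per-sample (column-wise) variant is used. Per-protein two-sided
two-sample t-tests (pooled variance) are Benjamini–Hochberg adjusted;
significance is q ≤ 0.05 plus an optional fold-change threshold. log2
fold change is the second group's mean minus the first (reference)
group's. With no missing values the result is seed-independent; with a
seed it is bit-reproducible.

One practical observation the synthetic runs make visible: with n = 3+3
and ~3% of proteins carrying a true ~2.5-fold effect among 1000, BH
adjustment at q ≤ 0.05 is strict — most affected members show raw
p < 0.05 but only the strongest pass the adjusted threshold. Larger
effects or more replicates move the adjusted counts up; the raw-p
enrichment over background is the more stable readout at this scale.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code, deterministic per seed; one
global seed fans out to per-stage child generators keyed by stage name
(CRC32 of the name mixed into the seed sequence), so stages can be
regenerated independently.

* **Toy genes** plant requested substitutions by exhaustive codon-table
  search (e.g. S→F via TCC→TTC) inside a designed tryptic context (R
  codons 6 upstream and 5 downstream), so every planted site is covered
  by an 11-residue peptide passing the default filters. The bundled
  reference system embeds the real tryptic contexts (and real CDS
  positions) of three well-characterized editing sites in otherwise
  synthetic filler.
* **PSM tables**: 500 spectra per site by default; each spectrum is the
  edited form with probability f (the planted fraction); log-normal
  spectrum intensities (σ = 0.5 on the natural-log scale), normal scores
  (Andromeda-like: mean 150, sd 25), MBR probability 0.05, fragment-ion
  coverage probability 0.9. At 500 spectra the intensity-ratio estimator
  recovers f within ±0.05.
* **Complexome maps**: 43 fractions, log-linear calibration from 1600 kDa
  (fraction 2) to 60 kDa (fraction 42) mirroring a 4.5–16% gradient-gel
  range; complexes at 200/450/1000/1500 kDa as Gaussian peaks (σ = 0.8
  fractions) with per-condition occupancy multipliers — the second
  condition depletes the holo-complex (×0.4) and supercomplex (×0.5) and
  accumulates the 200 kDa intermediate (×3), emulating disturbed
  assembly; uniform noise floor at 0.5% of the global maximum.
* **Quant matrices**: log2 intensities N(25, 2²) with replicate noise sd
  0.25, two groups of three; planted per-complex log2 fold changes;
  missingness (when enabled, up to 30%) applied preferentially to low
  intensities through a logistic curve centred two SDs below the mean.

Not emulated: raw spectra and search-engine behavior (scores are drawn,
not computed from spectra), retention time and ion mobility, interference
and co-fragmentation, protein inference ambiguity, gel-run distortions,
and biological covariance between complex members beyond shared
occupancy. Passing tests therefore demonstrate that the *pipeline logic*
recovers planted truths under the stated noise model, not that the
upstream identification stack would behave identically on real data.

## Numerical choices and degenerate inputs

* Mass comparisons: 1e-3 Da absolute; residue-delta identities hold to
  1e-4 Da. The mimicry window (±2 Da) is inclusive at the boundary.
* Proteoform deduplication keeps the first signature in enumeration
  order (fully edited first), so labels are deterministic.
* Zero-intensity degenerate cases: both-zero editing fractions return
  NaN with a warning; all-zero profiles are dropped at normalization;
  flat profiles yield no peaks; empty complexome input returns an empty
  map with a warning.
* Calibration requires ≥2 markers at distinct fractions and strict
  monotonicity; complex masses outside the marker range are an error in
  the simulator rather than an extrapolation.
* Problem sizes used by the test suite and analysis scripts (200 random
  proteins for the digestion oracle, 500 spectra per site, 1000 proteins
  for the null volcano) were chosen to make the statistical checks
  decisive while keeping a full run in the order of seconds.

## Known limitations

* The evidence rules automate the published *criteria*, but the original
  procedure included manual spectrum inspection; the mimicry screen here
  flags candidates instead of resolving them.
* Reference-based map comparison is a single global factor; viewers may
  use per-fraction or iterative schemes. The function boundary accepts
  alternatives.
* The ±2 Da mimicry screen considers modifications of the edited residue
  position only, not neighboring residues within the peptide.
* Editing-fraction estimates assume the two peptide forms ionize and
  fragment identically; real edited/unedited forms can differ in
  response, biasing the protein-level fraction relative to transcript
  frequencies.
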