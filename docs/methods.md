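# Methods

## Scope and model

`proformatch` implements the computational core of targeted proteoform
characterization by top-down mass spectrometry: a single candidate proteoform
is scored against a list of deconvoluted neutral monoisotopic fragment
masses. Everything upstream of that list — acquisition, charge deconvolution,
monoisotopic peak picking — is out of scope; the library consumes the flat
neutral-mass output such engines produce and never deals in charged m/z.

## Mass chemistry

All masses descend from one bundled monoisotopic atomic-mass table
(IUPAC/AME values, `data/atomic_masses.tsv`). Residue masses, glycan
monosaccharide token masses and formula-based modification shifts are derived
from elemental compositions at load time; there is no second copy of any
constant, so the additivity identity `mass(a+b) = mass(a) + mass(b)` and the
residue/composition identity hold by construction and are property-tested.
Glycan tokens (Hex, HexNAc, Fuc, NeuAc, NeuGc, Pent) carry *residue*
(dehydrated) masses because glycans attach and extend through glycosidic
bonds — so G1F = HexNAc4 Hex4 Fuc1 = 1606.5867 Da as a mass addition to the
asparagine it sits on. Cysteine carries no implicit alkylation: fixed
modifications (e.g. carbamidomethyl) are always an explicit user choice,
reflecting that top-down samples are frequently unalkylated.

The starter PTM catalogue (`data/ptm_catalogue.tsv`) is a representative,
deliberately small set of common PTMs, fixed modifications and N-glycans; it
is user-extensible by passing a merged name→Modification mapping to the
parser. It makes no claim to ontology completeness.

## ProForma subset

The parser accepts bare sequences, localized bracketed tags (signed mass
delta, `Formula:`, `Glycan:`, or a catalogue name), N/C-terminal tags with the
standard `-` delimiters, and global fixed modifications in `<[tag]@T1,T2>`
notation. Unlocalized, labile and range modifications are recognized and
rejected with errors naming the feature — mis-parsing or silently dropping a
tag is treated as worse than refusing it. INFO and ontology-accession tags
are likewise rejected rather than passed through, keeping the invariant that
every bracketed group either becomes a modification or raises.

Residue indexing is 0-based internally and 1-based in every user-facing
surface (ProForma round trips, .pcml positions, report rows, the SVG legend),
matching community convention ("G1F at N61"). Custom mass deltas print with
6 decimals; 6-decimal quantization is also the precision at which all mass
inputs enter the package (mass-list files, .pcml, the simulator), which is
what makes write→parse and write→read round trips reproduce masses exactly
rather than approximately.

## Fragmentation

Neutral fragment masses for a/b/c/x/y/z are computed from prefix sums of
per-residue masses (residue + localized mods + fixed mods at target
residues), with terminal modifications on the respective side and series
offsets derived from compositions (z is emitted as the z-radical z•,
standard for ETD/EThcD data; a config layer could add ±H variants but the
default stays z•). Complementarity `b_i + y_{n−i} = M` (and the fixed-offset
analogues for a/x, c/z) is the tested conservation law.

## Matching

A match requires `|m − s·Δ − f| / f ≤ tol·1e−6` for some integer shift
`s ∈ [−k, +k]`; Δ defaults to 1.00235 Da, the averagine inter-isotopologue
spacing by which deconvolution off-by-one errors displace a reported
monoisotopic mass (configurable, since the true spacing drifts slightly with
composition). The ppm denominator is always the theoretical mass; this is an
arbitrary but fixed reproducibility choice. Per observed mass one winner is
kept — smallest |s|, then smallest |ppm|, then lowest (series, index) — and
every per-pair candidate is retained for diagnostics, with the zero-shift
preference guaranteeing an isotope shift is never invoked when a direct match
exists. The matcher is vectorized over fragments×shifts per observed mass and
is regression-tested against an exhaustive brute-force oracle.

One-winner-per-observed (rather than many-to-many) is the documented design
choice: the match grid shows one row per matching fragment, but scoring needs
a deduplicated count, and a single deterministic winner keeps the two
consistent.

## Scoring

The P-score and PCS formulas are this package's own fully specified
definitions (the scores' lineage in the literature is not printed as
formulas); they are documented here so results are reproducible and the one
hard external constraint — enabling k shift steps must worsen both scores by
exactly the (1+2k) ion-type inflation — is honored and tested.

Null model: observed masses fall uniformly in (0, M). Each theoretical target
opens a window of width 2·m_i·tol·1e−6 and there are
F_eff = (n−1)·|series|·(1+2k) targets, giving per-mass chance probability
q_i = min(1, F_eff·2·m_i·tol·1e−6/M), λ = Σq_i, and
P-score = P(Poisson(λ) ≥ n_matched), computed through the regularized lower
incomplete gamma function; below ~1e−280 the tail is evaluated in log space
(log-sum-exp over 64 Poisson log-pmf terms, ample since terms decay by
λ/n ≪ 1 there) and `p_score` clamps to the smallest positive float while
`p_score_log10` carries the true magnitude. PCS = Σ_matched −log10(q_i):
each matched fragment contributes its information content under the same
null, so PCS rises with more and tighter matches and falls by log10(1+2k)
per match when shifts are enabled.

The per-observed window (δ_i from m_i, not a single averaged window) is the
chosen convention. The Monte-Carlo calibration test exploits that for
complementary series the mean fragment mass is ≈ M/2, making the model's
m_i-based windows agree with the fragment-based truth; calibration is
verified at 10,000 replicates against a window-interval simulation.

## Synthetic data

The generator plants a fraction of the true fragments with Gaussian *ppm*
noise (instrument error scales with mass), displaces a chosen number by
±1.00235 Da (the off-by-one error it exists to emulate), and adds uniform
decoys on (100, M) — the floor avoids physically silly sub-100 Da decoys. It
does **not** emulate isotope envelopes, intensity structure, correlated mass
error, or decoys clustered in the peptide mass-defect band; passing tests
therefore demonstrate correctness of the matching/scoring machinery under
the stated noise model, not performance on any real instrument's output.

The isotope-recovery experiment (1 ppm noise, 10% of planted fragments
displaced, 10 ppm tolerance, 100 replicates) is defined on the complementary
b/y pair. With four series enabled, roughly 0.7% of displaced masses land
within tolerance of a *different* fragment at shift 0 (near-isobaric
cross-series coincidences, e.g. c/z vs b/y sums); the winner rule's
zero-shift preference then assigns them there, which is the designed
behaviour of the matcher, not a recovery failure of the experiment. On b/y
the recovery dichotomy is exact: 100% with k=1, 0% with k=0.

Demo conditions (the acceptance run): the 119-residue Fc-like demo
proteoform with G1F at N61, b/y/c/z series, 60% of fragments observed at
1 ppm noise, 10% of those isotope-displaced, 300 decoys, 10 ppm tolerance,
k=1 — sizes chosen to resemble a well-fragmented antibody-subunit EThcD
experiment with a deconvolution mass list dominated by unassigned masses.

## Sessions and rendering

The .pcml dialect is this package's own versioned schema (the historical
format's layout is not published, so byte compatibility is explicitly
unclaimed; `schemaVersion` gates reads). Writing is canonical — fixed element
and attribute order, 6-decimal masses — so identical sessions produce
byte-identical files and write→read→write is a fixed point; unknown elements
under `<extensions>` are preserved opaquely. The share blob is the canonical
XML, base64url-encoded behind a CRC32 checksum: a portable, single-line
replacement for cloud-hosted share links with no service dependency.

SVG rendering is deterministic by construction (fixed-precision coordinates,
deterministic iteration): one monospace glyph per residue in rows of
20/25/30/40/50 (or `auto` = largest count fitting the target width at the
fixed 26 px cell), angled tick flags per covered cleavage site (upper/left =
N-terminal evidence, lower/right = C-terminal), highlighted modified residues
with a 1-based legend. Themes change colors only, never geometry. Output is
SVG 1.1, self-contained, script-free. Visual fidelity to any particular
application's drawing is not a goal; determinism and well-formedness are the
contract.

## Numerical and degenerate-input choices

- Tolerances: fragment conservation identities tested at 1e−9 Da; mass
  cross-checks against an independent library at 1e−6 Da.
- Ties in the winner rule are broken lexicographically by (series, index);
  with equal |shift| the smaller |ppm| wins, so +s vs −s ties cannot survive
  except at exact coincidences, which then resolve by fragment order.
- Empty observed list → empty match set, P-score 1.0, PCS 0.0 (defined, not
  an error). Proteoforms of length < 2 raise: there is no backbone to cleave.
- The CLI exposes defaults tol 10 ppm, series b/y/c/z, k=0, Δ=1.00235 and
  echoes all settings into report headers for provenance.

## Known limitations

- No internal fragments, neutral losses, intensity-aware matching, isotope
  envelopes or charge-state handling.
- The modification catalogue is a starter subset; unknown names fail loudly
  rather than guessing.
- P-score/PCS are this package's documented definitions, suitable for
  comparing hypotheses within the package — not bit-compatible with any other
  software's scores.
- Legacy .pcml files from other tools are not readable; only this package's
  dialect is supported.
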