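# Methods

## Scope and model

The package treats a *GAA* coding variant as a transformation of a single
supplied coding sequence (CDS) and interprets it at four levels: protein
consequence, diagnostic restriction-site change, functional severity, and
cohort allele statistics. Genomic (`g.`) coordinates, splicing simulation
from genomic sequence, and in-silico pathogenicity scores are out of scope;
canonical splice-site variants are flagged (`splice_canonical`) without a
protein prediction, because predicting the spliced product requires a
transcript model, not a CDS. The exon-skip helper makes the one assumption
that is standard in this setting: a variant at an acceptor/donor dinucleotide
(offset −1/−2 or +1/+2) causes skipping of the adjacent exon, whose
reading-frame effect then follows from the exon's CDS length alone.

## Consequence derivation

Coordinates are HGVS `c.`: 1-based, position 1 = A of ATG. Ambiguous
insertions/deletions/duplications are shifted to their most 3' position
before naming (the HGVS 3' rule); normalization never changes the edited
sequence, only its description, which is why the brute-force test oracle can
skip it. The engine edits the CDS, translates wild type and mutant with the
standard code up to the first stop, and compares the two translations
(stop written as `*`) position by position:

- identical translations → synonymous (`p.(=)`);
- first differing residue becomes `*` → nonsense, even when the DNA-level
  event shifts the frame (HGVS convention);
- single residue replaced, lengths equal → missense; replacement of residue
  1 of the start methionine → start loss (`p.Met1?`); replacement of the
  stop → stop loss (flagged, not named beyond `ext?`);
- in-frame length change → in-frame deletion/insertion with the affected
  span named after maximal common prefix/suffix matching (mixed events fall
  back to `delins` naming);
- frame-disrupting length change → frameshift `p.(ref)(pos)(new)fsTer N`,
  where N counts the new stop with the first altered residue as position 1;
  if the shifted frame reaches the end of the supplied CDS without a stop
  the result is `no_stop_found_frameshift` rather than a guess, since no
  3' UTR is available to scan.

Two `p.` dialects are emitted: modern (`Ter`, `fsTerN`) and the legacy
clinical style (`X`, `fsXN`) that older reports print; the legacy style is
the default so published names reproduce byte-for-byte. The parser also
accepts two legacy `c.` spellings seen in such reports: single-position
insertions (`c.1226insG` = insertion after base 1226) and truncated range
ends (`c.1411_14del` = `c.1411_1414del`, missing leading digits borrowed
from the start coordinate).

A deliberate taxonomy choice: a same-length multi-residue replacement
(possible only through delins inputs) is categorized `missense` with a
`delins` span name, rather than adding a category outside the standard set.

## Restriction diagnostics

Recognition sites are IUPAC patterns matched per position against the
degeneracy sets; both strands are scanned (cheap, and safe for user-supplied
non-palindromic enzymes) and reverse-strand hits are reported at their
forward-strand start. The gain/loss diff compares wild-type and mutant site
position sets; gained positions are mutant coordinates, lost positions
wild-type coordinates. The scan window is the supplied CDS (or any amplicon
the user passes instead): site creation is local, so the result is
window-independent except for sites straddling the window edge, which are
missed. Defaults are BfaI (`CTAG`) and SfcI (`CTRYAG`), both their own
IUPAC reverse complements.

## Severity rating

Normalization: M%Wt = 100·(mutant medium)/(wild-type medium), likewise
C%Wt for cell lysate. Classification always uses unrounded percentages;
*reporting* rounds half-up to 2 decimals below 10 and 1 decimal otherwise,
matching how such tables are printed. Replicate activities, when given, are
averaged first.

A band code is (quantity 1–5, quality 1–4). A threshold like "≥ 2,4" is met
only at sufficient quantity **and** normal apparent mass (quality 4) — a
band of the wrong size is not the protein the rule asks about; the floor
threshold (1,1) is met by anything.

The classes are evaluated most-severe-first; the first rule whose activity
ranges and band thresholds all hold wins:

| class | M%Wt | C%Wt | band requirements |
|---|---|---|---|
| A | ≤ 2 | ≤ 2 | all four exactly (1,1) |
| B | ≤ 2 | ≤ 5 | C110 ≥ (2,4) |
| C | ≤ 10 | 2 < C ≤ 10 | C110, C95, C76 ≥ (2,4) |
| D | 5–30 | 5–30 | M110 ≥ (2,4); C110, C95, C76 ≥ (3,4) |
| E | 30 < M ≤ 60 | 30 < C ≤ 60 | M110 ≥ (2,4); C110, C95, C76 ≥ (4,4) |
| F | > 60 | > 60 | all four ≥ (4,4) |

Most-severe-first ordering is what resolves the deliberate overlaps in the
printed ranges (B's C% 0–5 vs C's 2–10; C's M% 0–10 vs D's 5–30). The
E gate on the medium band is the relaxed (2,4): a variant with reduced but
normal-sized secreted precursor can still be E, while F demands fully
normal bands everywhere — the unique reading consistent with a
secretion-impaired variant rating `D/E` rather than `D/F` or a single class.

When no rule matches, the compartments are discordant and each axis is
rated on its own: the class whose activity range contains the value, ties
broken toward the range with the greater lower bound (5.47% in medium is D,
whose range starts at 5, not C, whose range starts at 0) and then toward
severity. Band evidence caps the per-axis calls symmetrically — A requires
absent protein, else B; F requires all-normal bands, else E. If both axes
agree after capping, that single class is returned; otherwise the ordered
pair is returned with `ambiguous=True` and printed with a slash (`D/E`).
The classifier is total: every activity pair in [0, ∞)² with any band
profile yields one or two classes.

## Cohort statistics

Cohort tables are one row per distinct allele per patient; a homozygous row
contributes two alleles, and loading fails unless every patient sums to
exactly two (an autosomal-recessive design check). Variants are keyed by
protein name when present, else by cDNA name (splice alleles). Known
pseudodeficiency alleles are excluded from pathogenic tallies and reported
separately, since they depress measured activity without causing disease.
External (published) allele counts merge additively and enlarge the
denominator; external alleles without an exon land in an `unspecified`
bucket so the per-exon sums still equal the total. Percentages round
half-up to one decimal. Domain spectra count *distinct variants* per domain
label; a splice allele with no domain of its own is counted in the
"catalytic-or-loss" aggregate when its skipped exon's residue span overlaps
the catalytic GH31 domain. Unmapped variants are listed under `unassigned`,
never dropped.

## Bundled data and the synthetic GAA model

`datasets.py` carries the published 12-patient IOPD cohort table
(18 rows, 24 alleles), the five-row COS-7 assay table, the 10-allele prior
Thai counts, and the pseudodeficiency list, typed in verbatim as TSV. The
bundled *gene model* and *domain map* are synthetic stand-ins, because exon
and domain boundaries are not part of that published record: exon 9 is
fixed at c.1327–1437 (111 nt — forced by the splice allele's in-frame
37-residue skip together with the exon-9 placement of c.1411/c.1437), all
other exon boundaries are chosen to satisfy every printed exon assignment,
the domain intervals (e.g. N-terminal β-sheet 156–336, catalytic GH31
347–726) to satisfy every printed domain assignment, and the 2859-bp
sequence itself is a seeded random CDS. Coordinate arithmetic on this model
is therefore faithful; base identities are not, which is why consequence
calls against the real reference sequence are left to users who supply it.

## Synthetic-data generators

All generators hang off a single integer seed (numpy `default_rng`); equal
configs give byte-identical outputs.

- **CDS**: ATG, then uniform draws from the 61 sense codons (no in-frame
  internal stop by construction), then a random stop. Default length 953
  codons, the scale of the real gene.
- **Gene model**: a noncoding first exon plus a uniform random partition of
  the CDS into the remaining exons (default 20 total).
- **Cohort**: default 12 patients. Each patient is homozygous with
  probability `hom_fraction` (default 0.3, the rough rate seen in
  consanguinity-containing IOPD cohorts) for one spectrum draw, else two
  independent draws; realized frequencies sit within binomial error of the
  targets. The default spectrum concentrates 0.375 on one variant,
  emulating a 9-of-24 hotspot allele.
- **Assay**: per-class templates (true M%, true C%, band profile) chosen
  inside each class's activity ranges with class-consistent bands; raw
  activities are wild-type × percent × a unit-mean lognormal factor with
  coefficient of variation `noise_cv`. The default CV of 0.07 is the
  replicate scatter typical of such transfection assays (≈7% on the
  wild-type lysate). The wild-type row is noiseless so a noiseless mutant
  recovers its template percentages exactly.

What the generators do *not* emulate: linkage between alleles and assay
values, CRIM immunology, batch effects between transfections, allele
dropout, or sequencing error. Tests passing on synthetic cohorts therefore
demonstrate counting/classification correctness under the stated noise
model, not robustness to real-world assay artefacts.

## Numerical choices

- Rounding is decimal half-up everywhere a value is printed (2 dp below 10
  and 1 dp otherwise for activity percentages; 1 dp for cohort
  percentages); classification and tallying always use exact/unrounded
  values.
- Lognormal noise uses σ² = ln(1 + CV²) with mean −σ²/2, so the factor has
  expectation exactly 1 at any CV.
- Ties in 3'-normalization are impossible by construction (the shift loop
  is deterministic); ties in the discordant-axis class lookup are broken as
  described above.
- Degenerate inputs: empty cohort files load as empty cohorts; a wild-type
  assay row with zero activity is an error (normalization undefined); a
  CDS without a terminal stop is reported as a validation violation, not an
  exception.

## Problem sizes in the routine battery

The stochastic batteries run at 1,000 round-trip variants, 1,000 random
CDS/variant oracle comparisons (10–80 codons each), a 13×13 activity grid
with sampled band profiles, 100 synthetic cohorts of 6 patients, and 200
noisy assay draws per class at 10% CV — sizes at which every battery is
stable across seeds while the whole suite stays fast.

## Known limitations

- Insertions 3' of the last CDS base and variants in the stop codon are
  edge cases handled conservatively (stop loss is flagged, not extended).
- The severity rules reproduce the published rating scheme as printed;
  where its prose and parentheticals disagree (the E-class medium gate),
  the reading adopted is the one consistent with the published worked
  examples, as argued above.
- `site_diff` compares site *positions*; for large indels a site that
  merely shifts coordinates would be reported as lost+gained. For the
  point-mutation screens this targets, positions are stable.
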