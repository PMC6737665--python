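# pompevar

A toolkit for interpreting coding variants of *GAA*, the acid
alpha-glucosidase gene deficient in Pompe disease (glycogen storage disease
type II). It is aimed at molecular-genetics labs and analysts who work with
infantile-onset Pompe disease (IOPD) cohorts: people who receive Sanger
variant calls as HGVS `c.` strings and need protein consequences, diagnostic
restriction-digest designs, functional severity ratings, and cohort allele
statistics — reproducibly, from plain text tables.

## What it computes

**HGVS consequence engine.** Parses `c.` descriptions (substitutions,
intronic substitutions like `c.1327-2A>G`, deletions including truncated
range spellings like `c.1411_14delGAGA`, insertions in both `c.1226insG`
and `c.1226_1227insG` dialects, duplications, delins), applies them to a
coding sequence after HGVS 3'-normalization, and names the protein effect
in both the modern (`p.Asp409GlyfsTer95`) and legacy clinical
(`p.Asp409GlyfsX95`) dialects. For a frameshift starting at residue $r$,
the reported stop distance $N$ in `fsTer N` counts the new stop with the
first altered residue as position 1.

**Gene model mapping.** 1-based CDS coordinates (position 1 = A of ATG);
codon of position $p$ is $\lceil p/3 \rceil$; exon and protein-domain
lookup; reading-frame consequence of exon skipping (a 111-nt exon skips in
frame, deleting 37 residues).

**Restriction diagnostics.** IUPAC-aware scanning of both strands for
recognition sites, and the gain/loss diff a PCR-RFLP screen is designed
from (BfaI `CTAG`, SfcI `CTRYAG` by default).

**Severity rating (classes A–F).** Transfection-assay activities are
normalized to percent of wild type, $M\%_{wt} = 100\,a_M/a_M^{wt}$ and
$C\%_{wt} = 100\,a_C/a_C^{wt}$, and combined with four western band codes
(M110, C110, C95, C76; each a quantity digit 1–5 and a quality digit 1–4)
in a most-severe-first rule cascade from class A (no protein, no activity —
a CRIM-negativity surrogate) to F (nonpathogenic). Discordant
medium/lysate activities yield an ambiguous pair such as `D/E`.

**Cohort allele spectrum.** Biallelic genotype tables are validated
(every patient carries exactly two alleles), tallied per variant / exon /
domain with pseudodeficiency alleles (p.Gly576Ser, p.Glu689Lys) excluded,
merged with published external counts, and summarized as hotspot fractions.

**Synthetic data.** Seeded generators for valid coding sequences, gene
models, biallelic cohorts with a target allele spectrum, and
class-consistent assay tables with multiplicative lognormal noise — every
stage of the pipeline is testable without any download.

## Worked example

Rate the bundled COS-7 transfection table (wild type plus four variants):

```sh
python -c "from pompevar import datasets; print(datasets.COS7_ASSAY_TSV)" > assay.tsv
pompevar rate --assay assay.tsv --wildtype "Wild type"
```

```
variant	m_pct_wt	c_pct_wt	class
Wild type	100.0	100.0	-
p.Ala261Thr	5.47	75.8	D/E
p.Tyr292X	0.0	0.0	B
p.Asp513Gly	0.0	0.76	B
p.Leu632Arg	0.08	0.02	B
```

p.Tyr292X, p.Asp513Gly and p.Leu632Arg keep an intracellular 110-kDa
precursor band at normal mass with ≤2% medium and ≤5% lysate activity, so
they rate class B (severe but CRIM-positive). p.Ala261Thr secretes poorly
(5.47% in medium, class-D range) while retaining 75.8% lysate activity
(class-F range, capped to E because secretion is subnormal), so the two
compartments disagree and the rating is the ambiguous pair `D/E`.

Consequence calls on a toy CDS (`ATGCCCGCTAAATAG`, protein MPAK):

```sh
pompevar consequence --cds toy.fa --variant "c.10A>T" --variant "c.6_7insA"
```

reports `c.10A>T` as nonsense `p.Lys4X` / `p.Lys4Ter` (codon 4 AAA→TAA)
and `c.6_7insA` as frameshift `p.Ala3SerfsX2` (new codon 3 is AGC = Ser;
the shifted frame hits a stop at the next codon, so $N=2$).

Cohort statistics from a genotype TSV plus prior published counts:

```sh
pompevar cohort --cohort cohort.tsv --external external.tsv \
    --hotspot-exon 14 --group "p.Asp645Glu,p.Asp645His"
```

On the bundled 12-patient IOPD cohort (24 alleles) merged with an earlier
10-allele report this prints, among other fields,
`"exon_14_fraction": {"count": 17, "total": 34, "percent": 50.0}` and
`"group_p.Asp645Glu_p.Asp645His": {"count": 11, "total": 34, "percent": 32.4}` —
exon 14 carries half of all mutant alleles and the p.Asp645Glu/His group
about a third, the regional screening hotspot.

## Layout

- `src/pompevar/gene_model.py` — CDS/exon/domain coordinate mapping
- `src/pompevar/hgvs.py` — variant parsing, editing, consequence naming
- `src/pompevar/restriction.py` — IUPAC site scanning and gain/loss diffs
- `src/pompevar/severity.py` — normalization and the A–F classifier
- `src/pompevar/cohort.py` — biallelic tallies, merges, domain spectra
- `src/pompevar/simulate.py` — seeded synthetic-data generators
- `src/pompevar/datasets.py` — bundled published tables and synthetic GAA model
- `src/pompevar/io.py`, `src/pompevar/cli.py` — file dialects and the CLI

See `docs/methods.md` for the model, rules, and design choices in detail.
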