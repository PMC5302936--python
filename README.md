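# tcrisk

In-silico fratricide / cross-reactivity risk screening for candidate
tumor-specific T-cell receptors (TCRs).

Engineering T cells with a transgenic TCR against a tumor antigen can fail
in a characteristic way: if the TCR cross-recognizes peptides presented on
the T cells themselves, the transduced cells kill each other during
expansion (*fratricide*). `tcrisk` implements the desk-side screen that
flags this risk before any transduction experiment, for immunologists and
TCR-engineering groups working with MHC class I restricted nonamer epitopes
(the motivating case is the HLA-A\*02:01 epitope ADRB3<sup>295</sup>,
GLIMGTFTL):

1. **Exchange-scan analysis.** An alanine/serine (or alanine/threonine)
   scan substitutes each position of the epitope in turn; IFNγ ELISpot
   counts measure whether the T cell still recognizes each variant. For
   each variant the background-subtracted activity relative to the original
   peptide is

   *r* = max(0, mean(variant) − mean(background)) / (mean(original) − mean(background)),

   and the position is called **abolished** (*r* < 0.25, crucial contact),
   **partial** (0.25 ≤ *r* < 0.75) or **unaffected** (*r* ≥ 0.75).
2. **Recognition motif.** The calls compress into a PROSITE-style pattern:
   crucial positions keep the original residue, tolerated positions become
   `X`, partially tolerated positions become a bracket class such as `[LA]`
   (original residue first). GLIMGTFTL yields `X-L-X-X-X-X-F-X-[LA]`.
3. **Proteome scan.** The motif is matched against every fixed-length
   window of a protein FASTA database; the number of *distinct* matching
   peptides is the TCR's **motif burden** — its pool of potential
   off-target epitopes.
4. **MHC binding scores.** Each matching peptide gets an additive
   position-specific scoring matrix (PSSM) score for the restricting HLA
   allele, score(p) = Σ<sub>i</sub> M[i, p<sub>i</sub>] (SYFPEITHI-style
   integer matrices).
5. **Risk report.** Candidate TCRs are compared by burden ratio and by a
   two-sample test on their score distributions (Mann–Whitney by default,
   unpaired two-tailed t-test selectable), and ranked by a composite index
   w<sub>b</sub>·log₁₀(burden+1) + w<sub>s</sub>·median(score)/max(score).
   A promiscuous motif (burden in the thousands) with strong predicted
   binders signals fratricide/cross-reactivity risk; a tightly constrained
   motif (tens of matches) does not.

A seeded synthetic-data module generates proteomes with planted motif
occurrences, noisy ELISpot tables and toy PSSMs with known ground truth, so
every stage is testable end to end.

## Worked example

Generate a synthetic dataset with known ground truth — 50 background
proteins, six copies of GLIMGTFTL and three of another motif carrier
planted, and an exchange-scan table whose planted truth is *abolished* at
positions 2 and 7 and *partial* at position 9:

```sh
$ tcrisk simulate --out-dir demo --seed 11 \
    --plant GLIMGTFTL 6 --plant KLPPDRFQA 3 \
    --call 2 abolished --call 7 abolished --call 9 partial
demo

$ tcrisk derive-motif demo/scan_table.tsv
X-L-X-X-X-X-F-X-[LA]

$ tcrisk scan demo/proteome.fasta "X-L-X-X-X-X-F-X-[LA]"
hits=13 unique_peptides=6 windows=12791

$ tcrisk risk \
    --tcr ADRB3 "X-L-X-X-X-X-F-X-[LA]"      demo/proteome.fasta demo/pssm.tsv \
    --tcr CHM1  "X-X-X-X-X-[ST]-W-W-[VT]"   demo/proteome.fasta demo/pssm.tsv
# TCR cross-reactivity risk report

| rank | TCR | risk index | burden | scored n | median score |
|---:|---|---:|---:|---:|---:|
| 1 | ADRB3 | 1.305 | 6 | 6 | 28.5 |
| 2 | CHM1 | 0.000 | 0 | 0 | - |

## Pairwise comparisons

- ADRB3 vs CHM1: burden 6 vs 0 (ratio inf, higher: ADRB3); distribution test skipped (insufficient n)
```

Reading the output: the derived motif reproduces the planted recognition
pattern exactly. The scan finds 13 matching windows — the 9 planted copies
plus 4 chance matches from the uniform background (12 791 windows × the
analytic match probability (1/20)·(1/20)·(2/20) = 2.5×10⁻⁴ ≈ 3 expected) —
collapsing to 6 distinct peptides, the ADRB3 burden. The CHM1-style motif
(`W-W` core) has no carriers in this database, so ADRB3 ranks first: its
risk index is log₁₀(6+1) + 28.5/62 ≈ 1.305, and the pairwise record shows
the burden asymmetry while skipping the distribution test for want of CHM1
scores.

The same steps are available as library calls (`parse_scan_table`,
`call_recognition`, `derive_motif`, `scan_database`, `score_set`,
`build_profile`, `rank_risk`) for use in notebooks and pipelines.

## File formats

- **Exchange-scan TSV**: columns `row_type position original_residue
  substituted_residue rep1..repN`; the `original` row carries the full
  peptide sequence in `original_residue`; optional `# name:` and
  `# pulse_concentration_uM:` comments.
- **Titration TSV**: `concentration_uM rep1..repN` rows plus one
  `background` row.
- **Motif patterns**: hyphen-separated `X`, residue letters, `[..]`
  inclusion and `{..}` exclusion classes (a dialect of PROSITE syntax;
  no repetition counts or terminal anchors).
- **PSSM TSV**: `# allele:` comment, header `position <residues>`, rows
  `P1..PL` with integer cells; blank cells fall back to the default score.
- **Reports**: JSON (lossless, with full parameter provenance) and a
  Markdown summary table.
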