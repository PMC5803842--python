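# ptbscan

Comparative-survey toolkit for plant **polypyrimidine tract-binding (PTB)
proteins** and their phloem-mobile target RNAs.

In potato, the chaperone-clade PTB proteins StPTB1/StPTB6 bind
cytosine/uracil (CU) tracts in the 3′ UTRs of mobile mRNAs such as *StBEL5*
and *POTH1*, stabilising them during long-distance transport to the sites
of tuber and root growth. Surveying other storage-root crops (sweet potato,
cassava, carrot, radish, sugar beet) for the same machinery involves a
fixed set of computations, and `ptbscan` packages them as a tested,
scriptable pipeline:

- **CU-motif scanning** — a CU motif is a *maximal* run of ≥ 3 contiguous
  pyrimidines containing at least one C and one U. Maximal runs cannot
  overlap, so counts are unambiguous. T is read as U; IUPAC ambiguity codes
  (including Y) never count as pyrimidines.
- **PTB-binding-region detection** — clusters of ≥ 4 consecutive CU motifs
  spanning ≤ 150 nt (first motif start to last motif end), the
  configuration sufficient for StPTB1/6 binding.
- **RRM/RNP detection and PTB typing** — reference RRM blocks are locally
  aligned to a candidate protein (BLOSUM62, gap open 10 / extend 1); hits
  with ≥ 40 % identity covering ≥ 60 % of the profile are assigned greedily
  without overlap, RNP1/RNP2 boxes are mapped through the alignment, and
  the qualifying-hit count gives the call: 4 RRMs → PTB1/6-type (CmRBP50
  chaperone clade), 3 RRMs → PTB7-type.
- **Orthologue ranking** — BLAST-style query coverage % and percent
  identity from the best local alignment, ranked by
  (coverage, identity, score).
- **Phylogeny** — per-column conservation categories against a
  two-sequence reference, p-distances (optionally Poisson-corrected to
  substitutions per site), neighbor-joining trees, midpoint rooting,
  Newick output.
- **Expression** — the Livak 2^−ΔΔCt method on replicated Ct tables:
  technical replicates averaged per biological replicate,
  ΔCt = Ct_target − Ct_reference, ΔΔCt against the calibrator-condition
  mean, fold = 2^−ΔΔCt with SE and a two-sided Student's *t* on ΔCt
  (stars at p < 0.05 / 0.01 / 0.001).
- **Synthetic data** — seeded generators with planted ground truth (UTRs
  with known motif counts, 3- and 4-RRM proteins, Ct tables with known
  folds, additive trees), so the entire pipeline runs and is testable with
  no download.

## Worked example

```python
from ptbscan.synthetic import gen_utr, gen_ct_table
from ptbscan.cu_motif import scan_cu_motifs, find_binding_regions, tabulate_motifs
from ptbscan.expression import delta_delta_ct, fold_change_table

rec, truth = gen_utr(length=503, n_motifs=17, seed=7)   # StBEL5-like 3' UTR
rep = scan_cu_motifs(rec, min_len=3)
print(tabulate_motifs([rep]).to_string(index=False))
for reg in find_binding_regions(rep, window=150, min_motifs=4):
    print(f"binding region {reg.start + 1}-{reg.end}: {reg.n_motifs} motifs")

table, _ = gen_ct_table(["BEL5like"], ["leaf", "root"], {"BEL5like": {"root": 4.0}},
                        noise_sd=0.2, seed=7)
print(fold_change_table(delta_delta_ct(table, "BEL5like", "GAPDH", "leaf"))
      .round(4).to_string(index=False))
```

prints

```
             seq_id  utr_length_nt  n_cu_motifs                            motif_spans
synthetic_utr_seed7            503           17  24-27;41-47;50-53;...;435-441;463-466
binding region 24-243: 9 motifs
binding region 165-466: 10 motifs
    gene condition   fold     se      p stars  n_bio
BEL5like      leaf 1.0000 0.0972    NaN    ns      3
BEL5like      root 4.5441 0.2058 0.0001   ***      3
```

The 503-nt synthetic UTR carries 17 planted CU motifs (the StBEL5 regime)
and the scanner reports exactly those 17, in 1-based inclusive spans. Two
dense clusters qualify as putative PTB-binding regions. The qPCR table was
generated with a true 4-fold leaf→root increase and Ct noise of 0.2
cycles; the recovered fold is 4.54 ± 0.21 (the calibrator is pinned at 1
by construction) with p < 0.001 on ΔCt.

The same stages are available from the shell:

```
ptbscan survey --seed 1 --out results/        # full synthetic survey + manifest
ptbscan scan-cu --in utrs.fasta --min-len 3 --out report.tsv --json report.json
ptbscan regions --in report.json --window 150 --min-motifs 4 --out regions.tsv
ptbscan rrm --in proteins.fasta --out hits.tsv
ptbscan ortho --query potato.fasta --candidates crop.fasta --out scores.tsv
ptbscan tree --aln ptb_aln.fasta --correction poisson --out tree.nwk
ptbscan ddct --in ct.tsv --ref GAPDH --calibrator leaf --out folds.tsv
```

Reports are deterministic for a fixed seed and configuration, and every
TSV carries a header comment with the parameters that produced it.

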