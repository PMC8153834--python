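# lcdscan

Composition-based identification and analysis of **low-complexity domains
(LCDs)** in protein sequences.

Low-complexity domains — regions composed predominantly of a small subset
of the 20 amino acids, such as the Q/N-rich prion-like domains and the
R/G/Y-rich phase-separating domains of yeast — are usually detected by
information-theoretic complexity or statistical-enrichment methods whose
cutoffs do not map onto biochemical features. `lcdscan` instead defines an
LCD directly by the two properties a biologist reasons about: the **percent
composition** of the residue(s) of interest and how **well-mixed** those
residues are across the region.

## The method

A window of fixed size *w* (default 20 aa) slides along each protein with
step 1. For a set *A* of residues of interest, each window is scored by:

- **Composition** `C = 100 · Σ_r n_r / w`, the percent of window residues
  belonging to *A* (per group, when several residue groups each carry
  their own threshold — "and" logic).
- **Linear dispersion** `s_norm`. The 1-based positions of set *A* and of
  its complement *B* are each augmented with the window termini (positions
  0 and *w*+1) and consecutive position differences `d_i` are taken; the
  population standard deviation *s* of the combined gap array is
  normalized against the extrema attainable at that window length and
  residue count:

  ```
  s_norm = 1 − (s − s_min) / (s_max − s_min)
  ```

  `s_max` comes from clustering all target residues at one terminus,
  `s_min` from spreading them as uniformly as possible (both constructions
  are validated exhaustively against brute-force enumeration in the test
  suite). `s_norm` ranges from 0 (fully clustered) to 1 (well mixed).

A window passes when every group meets its composition threshold and
`s_norm` meets the dispersion threshold (default 0.5); windows whose
combined composition exceeds the midpoint between the threshold and 100%
skip the dispersion check, and 100%-composition windows always pass.
Overlapping passing windows are merged, the merged span is trimmed from
both ends until its terminal residues belong to set *A*, and final
compositions and dispersion are recomputed on the trimmed domain.

Downstream statistics operate on the resulting LCD tables: partitioning a
primary LCD class into **subclasses** by the unambiguous second-most-
abundant residue, enrichment of each subclass against whole-proteome
window frequencies (`E_s = ln OR_s`, two-sided Fisher's exact test with
Bonferroni correction), the full 20 × 19 = 380 primary/secondary search
grid, co-occurring (non-overlapping, distinct-class) LCD counts per
protein, and per-class proteome LCD-content percentages with categorical
bins.

## Worked example

```python
from lcdscan import SearchCriteria, scan_proteome, window_composition

window_composition("QQQQQPGTRR", {"Q"})     # -> 50.0 (% Q in the window)

criteria = SearchCriteria(groups=[{"Q"}], thresholds=[40.0])   # w=20, d=0.5
table = scan_proteome([("toy", "AAAAA" + "Q" * 20 + "AAAAA")], criteria)
print(table.to_string(index=False))
```

```
protein_id      domain_sequence  start  end  Q_composition  final_s_norm class_label
       toy QQQQQQQQQQQQQQQQQQQQ      6   25          100.0           1.0           Q
```

All eleven 20-aa windows of the toy protein pass (the poly-Q core exceeds
the 70% midpoint, so dispersion is ignored), the windows merge into one
span covering the whole protein, and trimming removes the alanine flanks:
one domain at positions 6–25 with 100% Q composition.

From the shell, the same search and the downstream analyses:

```sh
lcdscan scan proteome.fasta -a QN_Y -c 40_10 -o prionlike.tsv   # multifaceted
lcdscan enrich proteome.fasta -p N                              # subclass enrichment
lcdscan grid proteome.fasta                                     # 380 pairwise searches
lcdscan cooccur prionlike.tsv                                   # co-occurrence counts
lcdscan content prionlike.tsv proteome.fasta                    # LCD content bins
lcdscan fixtures --plant N:30:3 --seed 7                        # synthetic proteome
```

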