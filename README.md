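# riconf

Evidence-architecture toolkit for transcription-factor regulatory
interactions (RIs): a declarative evidence catalog with independence
groups, an additive-evidence confidence calculus (weak → strong →
confirmed), high-throughput binding-peak-to-site mapping that enriches RI
evidence, recovery benchmarking of HT methods against classically
supported sites, and flexible gold-standard extraction with method
exclusion.

## Concepts

- **Evidence catalog** — each evidence code carries a category (classical /
  HT / nonexperimental), an independence group (1–7, or none), a base
  confidence level, and an aspect (binding vs function). Codes in the same
  group share methodological bias and never combine; codes from different
  groups are independent.
- **Confidence calculus** — an RI's base level is strong iff any binding
  code sits in group 1 or 2. Upgrade rules (data, not code) count distinct
  independence groups: two weak groups → strong; two strong groups →
  confirmed; two weak + one strong → confirmed; four weak groups →
  confirmed. Every upgrade is gated on the presence of function
  (expression) evidence. Arbitrary codes, categories, or groups can be
  excluded and the levels recomputed — the basis for non-circular gold
  standards.
- **Peak mapping** — HT peaks (ChIP-seq/-exo/-chip, gSELEX, DAP-seq) are
  normalized (reported ends, or a 200-nt window around the center), lifted
  between genome versions via an offset table, and matched to RI sites by
  strict containment; matching methods' codes are added to the RI and
  confidence is recomputed.
- **Recovery benchmark** — per-TF and pooled percentages of classical sites
  contained in same-TF peaks per method, compared with a Kruskal–Wallis
  test and Bonferroni-adjusted pairwise Mann–Whitney tests.
- **Synthetic corpora** — seeded generators plant per-method recovery
  probabilities and finite evidence mixes with enumerable confidence
  distributions, so the whole pipeline is testable offline.

## CLI

```sh
riconf catalog --export catalog.tsv            # built-in 12-code catalog
riconf simulate --seed 7 --out corpus/         # synthetic corpus + truth table
riconf map-peaks --riset corpus/riset.tsv --peaks corpus/peaks.tsv \
    --policy as_reported --out mapped.tsv --matches matches.tsv
riconf assign-confidence --riset mapped.tsv --exclude-category ht --out noht.tsv
riconf recover --riset corpus/riset.tsv --peaks corpus/peaks.tsv \
    --set classical --policy as_reported --out report.tsv --stats stats.tsv
riconf summarize --riset mapped.tsv --out summary.tsv --upset upset.tsv
```

Exit codes: 0 success, 1 validation error, 2 I/O error. Logs go to stderr,
data only to the declared output files.

## File formats

All formats are plain TSV. The RI-set dialect is a 22-column layout with
binding and function evidence-code lists in columns 21/22 (1-based);
column positions are remappable via `riconf.riset_io.Dialect`. Peak files
are BED-like (`dataset_id, tf_name, method, left, right, center,
genome_version, no_cutoff`); coordinates are 1-based inclusive everywhere.
Gold-standard writers emit a YAML provenance sidecar recording the filter
and exclusions applied.

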