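# svadist

Genome-wide distribution analysis of SVA (SINE–VNTR–Alu) retrotransposons:
megabase-window density profiling, density–transcript correlation, calling of
SVA-dense loci, locus gene-content characterisation, subfamily composition
fold changes, and cross-referencing of KRAB zinc-finger protein (KRAB-ZFP)
binding enrichment against the dense loci. A seeded synthetic-annotation
generator makes every analysis reproducible end to end without external data.

## Scientific background

SVA elements are the youngest family of hominid-specific retrotransposons,
divided into seven subfamilies: the evolutionarily old A, B and C, and the
young D, E, F and F1. Reference SVA insertions are not uniformly distributed
along the genome. Binning annotations into 1 Mb windows reveals that SVA
density broadly tracks transcript density — consistent with their preference
for gene-rich, transcriptionally active chromatin — while a small number of
windows carry far more elements than the coupling predicts. Those SVA-dense
windows coincide with zinc-finger (ZNF) gene clusters, most prominently the
chromosome 19 KRAB-ZFP clusters; the KRAB-ZFPs whose ChIP-exo binding is most
enriched on old SVA subfamilies are themselves encoded inside the dense loci,
a signature of an ongoing host–retrotransposon arms race. Polymorphic
insertions (RIPs, retrotransposon insertion polymorphisms) show the same
qualitative coupling to transcript density.

`svadist` implements that analysis chain as a library and CLI:

1. **annotation I/O** — BED6 / TSV / RepeatMasker element parsing with
   subfamily normalisation, split-record merging, transcript and RIP readers,
   and log10-space p-value parsing that survives values below the double
   underflow limit (e.g. `1.14 × 10^−320`).
2. **windowed counts** — exact per-window tallies (start-coordinate rule) of
   elements by subfamily and age class, transcripts and RIPs.
3. **distribution analysis** — Pearson/Spearman density–transcript
   correlations per chromosome and genome-wide; threshold-based dense-window
   flagging (≥ 4 old or ≥ 6 young elements per Mb) and merging into
   `old` / `young` / `both` cluster calls.
4. **locus composition** — gene/ZNF content summaries of called loci and
   subfamily composition fold changes versus the genome-wide shares.
5. **ZFP enrichment** — significance filtering of a binding-enrichment table
   (p ≤ 1e-20) and dense-locus cross-referencing, including the
   old-subfamily-binder containment check.
6. **synthetic data** — a seeded generator producing transcript, element and
   RIP annotations with configurable density coupling and planted dense
   clusters, plus a cluster-recovery experiment against the ground truth.

The package bundles four small published reference tables (hg19): the
15-protein KRAB-ZFP SVA binding-enrichment table derived from the Imbeault
et al. (2017) ChIP-exo screen, the SVA-dense locus intervals, per-subfamily
SVA counts at three 1 Mb ZNF loci, and the genome-wide SVA subfamily
composition.

## Worked example

Generate a synthetic genome (three chromosomes, 45 Mb total) with one planted
old-subfamily cluster and one young cluster, then run the full analysis:

```sh
$ svadist simulate --seed 7 --outdir sim
wrote 87 elements, 1247 transcripts, 20 RIPs to sim

$ svadist run-all --chrom-sizes sim/chrom.sizes --elements sim/elements.bed \
    --transcripts sim/transcripts.tsv --rips sim/rips.bed --outdir out
```

`out/clusters.bed` recovers both planted clusters with the correct age
classes (columns: chrom, start, end, class, element count):

```text
chrS1	5000000	9000000	old	43	.
chrS2	3000000	4000000	young	18	.
```

which matches `sim/ground_truth.json` (planted: chrS1 windows 5–8 `old`,
chrS2 window 3 `young`). `out/cluster_locus_summaries.tsv` characterises the
called loci:

```text
locus	n_genes	n_transcripts	n_znf_genes	pct_znf	n_krab_znf	n_sva_total	transcripts_per_sva	genes_per_sva
chrS1:5000001-9000000	73	144	1	1.37	.	43	3.35	1.70
chrS2:3000001-4000000	9	18	0	0.00	.	18	1.00	0.50
```

and `out/correlations.tsv` holds the per-chromosome and genome-wide
density–transcript correlations (at 45 windows the genome-wide r for this
small example is near zero, −0.003516; the coupling becomes visible at the
default study scale of 500 windows — see the reproduction section below).

The published KRAB-ZFP binding-enrichment table ships with the package and is
the default input of the `zfp` subcommand:

```sh
$ svadist zfp --outdir zfp_out
zfp_out/zfp_report.tsv
{"n_significant": 15, "n_in_dense": 6, "pct_in_dense": 40.0, "old_binder_containment": true}
```

Fifteen proteins pass the p ≤ 1e-20 cutoff on at least one SVA subfamily, six
of them (40%) lie inside SVA-dense loci, and every old-subfamily binder is
contained in a dense locus.

Every output table starts with a `# svadist v… config=…` header hashing the
effective configuration; reruns with identical inputs are byte-identical.

## Documentation

See `docs/methods.md` for the model, parameter defaults and their rationale,
numerical conventions, and limitations.
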