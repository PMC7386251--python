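# File formats

All tabular formats are tab-separated text with a header row. Gene and
sample identifiers are opaque, case-sensitive strings and are never parsed
as numbers. Missing cells round-trip as empty fields, never as 0. Lines
starting with `#` are comments in edge-list files.

## Network edge list

Columns: `regulator`, `target`, optional `sign`
(`activation`/`inhibition`/`unsigned`), optional `weight` (a correlation in
[−1, 1] or a conditional probability in [0, 1]). One edge per row;
self-loops are dropped with a warning; duplicate (regulator, target) rows
keep the first occurrence. Undirected coexpression lists use the same
columns with each pair stored once (`dialect=undirected_edges` on read).

## Expression matrix

Genes as rows, samples as columns; first column `gene`, header row of
sample identifiers. Used for reference panels, cell-line basal profiles,
and clinical transcriptomes alike.

## Screen scores

Same genes × columns layout, one file per metric (CERES, BAGEL, or zGARP —
named at read time, not stored in the file). Missing scores allowed.

## Dependency labels

Columns: `gene`, `cell_line`, `label` (1 = dependency, 0 = independency),
`score` (the source screen score), `metric`.

## Prediction scores

Columns: `sample`, `gene`, `score` (class probability in [0, 1]).

## Donor manifest

Columns: `sample`, `donor`, `role` (`tumor` or `normal`); optional
pass-through subtype columns (e.g. `ER`, `PR`, `Her2`).

## Variants

Columns: `sample`, `gene`, `variant_class` (`nonsense`, `frameshift_indel`,
`missense`, `silent`, `other`), `position` (1-based, MAF convention),
`substitution` (amino-acid change; present iff missense), `zygosity`
(`heterozygous`/`homozygous`), `vaf` in [0, 1]. A converter accepts standard
MAF columns (`Hugo_Symbol`, `Variant_Classification`, `t_alt_count`,
`t_depth` → VAF).

## Copy-number codes

Genes × samples matrix of integers in {−2, −1, 0, 1, 2} (GISTIC-style
thresholded coding: homozygous deletion … high-level amplification).

## Run configuration

A single YAML file mirroring `deepdep.config.RunConfig`; unknown keys are
rejected. Every CLI run appends a JSON-lines record (`run_log.jsonl`) with
its subcommand, arguments, and seeds next to its outputs.
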