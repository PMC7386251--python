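"""TSV round-tripping for all public table formats.

All tabular formats are tab-separated with documented headers.  Gene
identifiers are always read as strings (never parsed as numbers), and
missing cells round-trip as missing, never as 0.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mutations import VARIANT_COLUMNS, VariantRecord, frame_to_variants, variants_to_frame
from .screens import LABEL_COLUMNS, ScreenScoreTable


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes as rows, samples as columns, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene identifiers in {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_screen(path: str | Path, metric: str) -> ScreenScoreTable:
    return ScreenScoreTable(scores=read_expression(path), metric=metric)


def write_screen(table: ScreenScoreTable, path: str | Path) -> None:
    write_expression(table.scores, path)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cell_line": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns {sorted(missing)}")
    return df[LABEL_COLUMNS]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels[LABEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Donor manifest: sample, donor, role (tumor/normal), optional subtype flags."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "donor", "role"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    bad = set(df["role"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"manifest roles outside tumor/normal: {sorted(bad)}")
    return df


def read_variants(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "substitution": str})
    return frame_to_variants(frame)


def write_variants(cohort: list[VariantRecord], path: str | Path) -> None:
    variants_to_frame(cohort).to_csv(path, sep="\t", index=False)
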