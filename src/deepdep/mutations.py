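"""Somatic-mutation classes and dependency-association statistics.

Inactivating variants (nonsense mutations and frameshift insertions or
deletions) are split by zygosity call and variant allele frequency (VAF):
heterozygous calls with VAF < 40% are heterozygous loss-of-function (hetLOF);
homozygous calls, or heterozygous calls with VAF > 50%, are homozygous LOF
(homoLOF); heterozygous calls with VAF in [40%, 50%] fall in an unclassified
gap.  Putative gain-of-function (GOF) mutations are identical missense
substitutions recurring in two or more samples; putative tumor suppressors
carry inactivating mutations in five or more samples.  Known oncogenes whose
variants are exclusively silent serve as negative controls.  Differential
dependency between mutant and wild-type groups is compared with two-sample
Kolmogorov-Smirnov and Student's t tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("nonsense", "frameshift_indel", "missense", "silent", "other")
INACTIVATING = ("nonsense", "frameshift_indel")
ZYGOSITIES = ("heterozygous", "homozygous")

HET_LOF_VAF_MAX = 0.40  # strict: VAF < 40% -> hetLOF
HOMO_LOF_VAF_MIN = 0.50  # strict: VAF > 50% (heterozygous call) -> homoLOF

COPY_NUMBER_CODES = {
    -2: "homozygous_deletion",
    -1: "heterozygous_deletion",
    0: "normal",
    1: "low_amplification",
    2: "high_amplification",
}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call with zygosity and VAF (1-based position, MAF convention)."""

    sample: str
    gene: str
    variant_class: str
    zygosity: str
    vaf: float
    position: Optional[int] = None
    substitution: Optional[str] = None  # amino-acid change, required for missense

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.variant_class == "missense" and not self.substitution:
            raise ValueError("missense record requires an amino-acid substitution")
        if self.variant_class != "missense" and self.substitution:
            raise ValueError("substitution only allowed on missense records")


def classify_lof(record: VariantRecord) -> str:
    """hetLOF / homoLOF / none for one inactivating variant.

    Heterozygous calls with VAF in the printed [40%, 50%] gap stay
    unclassified ("none"); no interpolation.
    """
    if record.variant_class not in INACTIVATING:
        raise ValueError(
            f"classify_lof expects an inactivating variant, got {record.variant_class!r}"
        )
    if record.zygosity == "homozygous":
        return "homoLOF"
    if record.vaf < HET_LOF_VAF_MAX:
        return "hetLOF"
    if record.vaf > HOMO_LOF_VAF_MIN:
        return "homoLOF"
    return "none"


def find_gof(cohort: Iterable[VariantRecord], min_samples: int = 2) -> dict[str, set[tuple]]:
    """Recurrent missense substitutions: same gene, position, and amino-acid
    change in at least ``min_samples`` distinct samples."""
    carriers: dict[tuple, set[str]] = {}
    for rec in cohort:
        if rec.variant_class != "missense":
            continue
        key = (rec.gene, rec.position, rec.substitution)
        carriers.setdefault(key, set()).add(rec.sample)
    out: dict[str, set[tuple]] = {}
    for (gene, pos, sub), samples in carriers.items():
        if len(samples) >= min_samples:
            out.setdefault(gene, set()).add((pos, sub))
    return out


def gof_carriers(cohort: list[VariantRecord], min_samples: int = 2) -> set[tuple[str, str]]:
    """(sample, gene) pairs carrying a recurrent (GOF) missense substitution."""
    recurrent = find_gof(cohort, min_samples=min_samples)
    pairs = set()
    for rec in cohort:
        if rec.variant_class != "missense":
            continue
        if (rec.position, rec.substitution) in recurrent.get(rec.gene, ()):
            pairs.add((rec.sample, rec.gene))
    return pairs


def putative_tsg(
    cohort: Iterable[VariantRecord],
    min_samples: int = 5,
    known_tsgs: Iterable[str] = (),
) -> set[str]:
    """Genes inactivated in >= ``min_samples`` distinct samples, plus known TSGs."""
    hit_samples: dict[str, set[str]] = {}
    for rec in cohort:
        if rec.variant_class in INACTIVATING:
            hit_samples.setdefault(rec.gene, set()).add(rec.sample)
    putative = {g for g, s in hit_samples.items() if len(s) >= min_samples}
    return putative | set(known_tsgs)


def silent_only_oncogenes(
    cohort: Iterable[VariantRecord], known_oncogenes: Iterable[str]
) -> set[str]:
    """Known oncogenes whose cohort variants are exclusively silent.

    Oncogenes with any nonsynonymous variant are excluded; oncogenes with no
    variant at all are excluded too (at least one silent mutation required).
    """
    silent: set[str] = set()
    nonsilent: set[str] = set()
    for rec in cohort:
        if rec.variant_class == "silent":
            silent.add(rec.gene)
        else:
            nonsilent.add(rec.gene)
    return (set(known_oncogenes) & silent) - nonsilent


def map_copy_number(code: int) -> str:
    """Five-level thresholded copy-number class for a GISTIC-style integer code."""
    try:
        return COPY_NUMBER_CODES[int(code)]
    except KeyError:
        raise ValueError(f"copy-number code {code} outside {{-2..2}}") from None


def classify_cohort(
    cohort: list[VariantRecord],
    gof_min_samples: int = 2,
) -> pd.DataFrame:
    """One mutation class per (sample, gene): homoLOF > hetLOF > GOF precedence.

    A homozygous hit dominates biologically when one pair carries several
    records; pairs matching no class are omitted.
    """
    gof_pairs = gof_carriers(cohort, min_samples=gof_min_samples)
    rank = {"homoLOF": 3, "hetLOF": 2, "GOF": 1}
    best: dict[tuple[str, str], str] = {}
    for rec in cohort:
        classes = []
        if rec.variant_class in INACTIVATING:
            lof = classify_lof(rec)
            if lof != "none":
                classes.append(lof)
        if (rec.sample, rec.gene) in gof_pairs and rec.variant_class == "missense":
            classes.append("GOF")
        for cls in classes:
            key = (rec.sample, rec.gene)
            if key not in best or rank[cls] > rank[best[key]]:
                best[key] = cls
    rows = [
        {"sample": s, "gene": g, "mutation_class": c} for (s, g), c in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "mutation_class"])


def compare_mutant_wildtype(
    diff: pd.DataFrame,
    classes: pd.DataFrame,
    target_class: str,
    genes: Optional[Iterable[str]] = None,
) -> dict:
    """KS and t statistics of differential dependency, mutant vs wild type.

    ``diff`` has columns donor/gene/diff (tumor minus normal score); the
    mutant group is the (donor, gene) pairs assigned ``target_class``, the
    wild-type group the remaining pairs on the same genes.  ``genes``
    restricts the gene universe (e.g. to pre-filter genes carrying LOF or
    GOF mutations before a copy-number comparison).
    """
    mutant_pairs = {
        (r.sample, r.gene)
        for r in classes.itertuples()
        if r.mutation_class == target_class
    }
    if genes is not None:
        genes = set(genes)
        diff = diff[diff["gene"].isin(genes)]
    mutant_genes = {g for _, g in mutant_pairs}
    pool = diff[diff["gene"].isin(mutant_genes)]
    is_mutant = [
        (donor, gene) in mutant_pairs for donor, gene in zip(pool["donor"], pool["gene"])
    ]
    mutant = pool.loc[is_mutant, "diff"].to_numpy(dtype=float)
    wild = pool.loc[np.logical_not(is_mutant), "diff"].to_numpy(dtype=float)
    if len(mutant) < 2 or len(wild) < 2:
        raise ValueError(f"fewer than 2 donors in a group for class {target_class!r}")
    ks = stats.ks_2samp(mutant, wild)
    tt = stats.ttest_ind(mutant, wild)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "t_statistic": float(tt.statistic),
        "t_p": float(tt.pvalue),
        "n_mutant": int(len(mutant)),
        "n_wildtype": int(len(wild)),
    }


# ---------------------------------------------------------------------------
# tabular I/O

VARIANT_COLUMNS = ["sample", "gene", "variant_class", "position", "substitution", "zygosity", "vaf"]

_MAF_CLASS_MAP = {
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift_indel",
    "Frame_Shift_Del": "frameshift_indel",
    "Missense_Mutation": "missense",
    "Silent": "silent",
}


def variants_to_frame(cohort: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample": r.sample,
            "gene": r.gene,
            "variant_class": r.variant_class,
            "position": r.position,
            "substitution": r.substitution,
            "zygosity": r.zygosity,
            "vaf": r.vaf,
        }
        for r in cohort
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def frame_to_variants(frame: pd.DataFrame) -> list[VariantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        pos = None if pd.isna(row.position) else int(row.position)
        sub = None if (pd.isna(row.substitution) or row.substitution == "") else str(row.substitution)
        records.append(
            VariantRecord(
                sample=str(row.sample),
                gene=str(row.gene),
                variant_class=str(row.variant_class),
                position=pos,
                substitution=sub,
                zygosity=str(row.zygosity),
                vaf=float(row.vaf),
            )
        )
    return records


def from_maf(maf: pd.DataFrame, zygosity_column: str = "zygosity") -> list[VariantRecord]:
    """Thin converter from standard MAF columns.

    Maps Hugo_Symbol / Variant_Classification / Protein_position /
    HGVSp_Short, and derives VAF as t_alt_count / t_depth.  Rows with variant
    classes outside the recognised set become class ``other``.
    """
    records = []
    for row in maf.itertuples(index=False):
        d = row._asdict()
        cls = _MAF_CLASS_MAP.get(str(d.get("Variant_Classification")), "other")
        vaf = float(d["t_alt_count"]) / float(d["t_depth"])
        sub = d.get("HGVSp_Short") if cls == "missense" else None
        pos = d.get("Protein_position")
        records.append(
            VariantRecord(
                sample=str(d["Tumor_Sample_Barcode"]),
                gene=str(d["Hugo_Symbol"]),
                variant_class=cls,
                position=None if (pos is None or pd.isna(pos)) else int(pos),
                substitution=None if sub is None or pd.isna(sub) else str(sub),
                zygosity=str(d.get(zygosity_column, "heterozygous")),
                vaf=vaf,
            )
        )
    return records
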