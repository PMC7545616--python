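"""Rare-variant filters: dominant-family shared-variant screen and a
simplified trio de novo screen.

The dominant screen keeps variants that are (1) nonsynonymous (excluding
in-frame insertions/deletions) and shared by every affected exome,
(2) absent from dbSNP, (3) at frequency <= 1e-5 in a reference
subpopulation, and (4) CADD-scored 15 or more. The trio screen keeps
"qualifying" genotypes: an alternate allele in the proband with both
parents confidently homozygous reference, below a control-frequency cap.

Tables are pandas DataFrames with fixed annotation columns
(``chrom, pos, ref, alt, consequence, in_dbsnp, pop_freq, cadd``) and one
``gt_<sample>`` column per sample holding VCF diploid genotype strings.
Every dropped record is tagged with the *first* criterion it failed, so
reason counts always sum to the number dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InputError

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "FilterCriteria",
    "FilterResult",
    "filter_dominant_shared",
    "detect_de_novo",
]

# functional classes counted as nonsynonymous before class exclusions
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "missense",
        "stop_gain",
        "stop_loss",
        "start_loss",
        "frameshift",
        "splice_site",
        "inframe_insertion",
        "inframe_deletion",
    }
)

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "in_dbsnp",
    "pop_freq",
    "cadd",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the dominant-family screen.

    ``missing_freq_passes``: a variant absent from the population database is
    treated as frequency 0 (novelty is evidence of rarity).
    ``missing_cadd_passes``: an unscored variant cannot meet a minimum score,
    so by default it fails.
    """

    require_shared_in: tuple[str, ...]
    max_pop_freq: float = 1e-5
    min_cadd: float = 15.0
    exclude_consequences: tuple[str, ...] = (
        "synonymous",
        "inframe_insertion",
        "inframe_deletion",
    )
    require_absent_dbsnp: bool = True
    missing_freq_passes: bool = True
    missing_cadd_passes: bool = False

    def __post_init__(self) -> None:
        if not self.require_shared_in:
            raise InputError("require_shared_in must list >= 1 sample")
        if not np.isfinite(self.max_pop_freq) or not np.isfinite(self.min_cadd):
            raise InputError("thresholds must be finite")


@dataclass
class FilterResult:
    """Retained records plus an audit trail of first-failure reasons."""

    retained: pd.DataFrame
    drop_reasons: pd.Series  # index = dropped row index, value = reason
    reason_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_dropped(self) -> int:
        return len(self.drop_reasons)


def _gt_column(table: pd.DataFrame, sample: str) -> pd.Series:
    col = f"gt_{sample}"
    if col not in table.columns:
        raise InputError(f"no genotype column for sample {sample!r} ({col})")
    return table[col].astype(str)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"variant table missing columns: {missing}")
    if table["alt"].astype(str).str.contains(",").any():
        raise InputError(
            "multi-allelic records detected: split each ALT onto its own row"
        )


def _is_called(gt: pd.Series) -> pd.Series:
    return ~gt.str.contains(r"\.", regex=True)


def _has_alt(gt: pd.Series) -> pd.Series:
    norm = gt.str.replace("|", "/", regex=False)
    return _is_called(gt) & norm.str.split("/").apply(lambda a: "1" in a)


def _is_hom_ref(gt: pd.Series) -> pd.Series:
    norm = gt.str.replace("|", "/", regex=False)
    return norm.isin(["0/0"])


def _finish(
    table: pd.DataFrame, keep: pd.Series, reason: pd.Series
) -> FilterResult:
    dropped = reason[~keep]
    counts = dropped.value_counts().to_dict()
    return FilterResult(
        retained=table[keep].copy(),
        drop_reasons=dropped,
        reason_counts={str(k): int(v) for k, v in counts.items()},
    )


def filter_dominant_shared(
    table: pd.DataFrame, criteria: FilterCriteria
) -> FilterResult:
    """Dominant-family screen on a pre-split annotated variant table.

    Criteria are applied in order — shared genotype, nonsynonymous class,
    dbSNP absence, population frequency, CADD — and the first failure is
    recorded per dropped record.
    """
    _check_table(table)
    n = len(table)
    keep = pd.Series(True, index=table.index)
    reason = pd.Series("", index=table.index, dtype=object)

    def fail(mask: pd.Series, tag: str) -> None:
        newly = mask & keep
        reason[newly] = tag
        keep[newly] = False

    shared = pd.Series(True, index=table.index)
    for sample in criteria.require_shared_in:
        shared &= _has_alt(_gt_column(table, sample))
    fail(~shared, "not_shared")

    consequence = table["consequence"].astype(str)
    nonsyn = consequence.isin(NONSYNONYMOUS_CLASSES) & ~consequence.isin(
        criteria.exclude_consequences
    )
    fail(~nonsyn, "consequence")

    if criteria.require_absent_dbsnp:
        fail(table["in_dbsnp"].astype(bool), "dbsnp")

    freq = pd.to_numeric(table["pop_freq"], errors="coerce")
    freq = freq.fillna(0.0 if criteria.missing_freq_passes else np.inf)
    fail(freq > criteria.max_pop_freq, "frequency")

    cadd = pd.to_numeric(table["cadd"], errors="coerce")
    cadd = cadd.fillna(np.inf if criteria.missing_cadd_passes else -np.inf)
    fail(cadd < criteria.min_cadd, "cadd")

    result = _finish(table, keep, reason)
    assert result.n_retained + result.n_dropped == n
    return result


def detect_de_novo(
    table: pd.DataFrame,
    proband: str,
    parents: tuple[str, str],
    control_max_freq: float = 0.0,
) -> FilterResult:
    """Trio screen for qualifying de novo genotypes.

    Retains records where the proband carries an alternate allele, both
    parents are *called* homozygous reference (an uncalled parent
    disqualifies — a conservative rule), and the population frequency does
    not exceed ``control_max_freq`` (missing treated as 0).
    """
    _check_table(table)
    gt_pro = _gt_column(table, proband)
    gt_f = _gt_column(table, parents[0])
    gt_m = _gt_column(table, parents[1])

    keep = pd.Series(True, index=table.index)
    reason = pd.Series("", index=table.index, dtype=object)

    def fail(mask: pd.Series, tag: str) -> None:
        newly = mask & keep
        reason[newly] = tag
        keep[newly] = False

    fail(~_has_alt(gt_pro), "not_in_proband")
    fail(~(_is_called(gt_f) & _is_called(gt_m)), "parent_uncallable")
    fail(~(_is_hom_ref(gt_f) & _is_hom_ref(gt_m)), "inherited")

    freq = pd.to_numeric(table["pop_freq"], errors="coerce").fillna(0.0)
    fail(freq > control_max_freq, "frequency")

    return _finish(table, keep, reason)
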