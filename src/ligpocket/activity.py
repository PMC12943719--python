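"""Activity-table housing, SAR metrics, and two-class comparisons.

The packaged activity table (``data/activity.tsv``) carries per-compound
IC50 values (nM) for the enzyme subtype and cellular assays plus the
in-vivo maximal-not-emetic-dose column. Missing cells (``nd``) are
absent values, never zeros. Class membership for the modeling comparison
is a fixed 8-vs-8 list of compound ids with IC50-range fallbacks.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ActivityTableError, ClassDefinitionError

ASSAY_FIELDS = (
    "ic50_pde4b1",
    "ic50_pde4a4",
    "ic50_pde4d3",
    "ic50_harbs",
    "ic50_tnfa_hwb",
    "ic50_tnfa_hpbmc",
    "ic50_caco2",
)

_TSV_COLUMNS = {
    "pde4b1_nM": "ic50_pde4b1",
    "pde4a4_nM": "ic50_pde4a4",
    "pde4d3_nM": "ic50_pde4d3",
    "harbs_nM": "ic50_harbs",
    "tnfa_hwb_nM": "ic50_tnfa_hwb",
    "tnfa_hpbmc_nM": "ic50_tnfa_hpbmc",
    "caco2_nM": "ic50_caco2",
    "mned_mgkg": "mned_ferret",
}

_MISSING_TOKENS = {"", "nd", "na", "n.d.", "none", "-"}

SERIES_VALUES = ("2", "3", "4", "5", "other", "reference")


@dataclass
class ActivityRecord:
    compound_id: str
    series: str
    ic50_pde4b1: float | None = None
    ic50_pde4a4: float | None = None
    ic50_pde4d3: float | None = None
    ic50_harbs: float | None = None
    ic50_tnfa_hwb: float | None = None
    ic50_tnfa_hpbmc: float | None = None
    ic50_caco2: float | None = None
    mned_ferret: float | None = None

    def __post_init__(self):
        if self.series not in SERIES_VALUES:
            raise ActivityTableError(
                f"{self.compound_id}: unknown series {self.series!r}"
            )
        for name in ASSAY_FIELDS + ("mned_ferret",):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ActivityTableError(
                    f"{self.compound_id}: {name} must be positive, got {value}"
                )

    def assay(self, name: str) -> float | None:
        key = name if name.startswith("ic50_") else f"ic50_{name.lower()}"
        if key not in ASSAY_FIELDS:
            raise KeyError(f"unknown assay {name!r}")
        return getattr(self, key)


@dataclass
class ClassDefinition:
    """Active (A) vs low-active (I) modeling classes."""

    active_members: tuple[str, ...] = (
        "Roflumilast", "2c", "2e", "2f", "2n", "2p", "3a", "3k",
    )
    inactive_members: tuple[str, ...] = (
        "Rolipram", "2i", "2h", "2o", "4f", "5d", "7", "10a",
    )
    active_range: tuple[float, float] = (0.69, 19.54)
    inactive_range: tuple[float, float] = (520.0, 6700.0)

    def __post_init__(self):
        overlap = set(self.active_members) & set(self.inactive_members)
        if overlap:
            raise ClassDefinitionError(f"compounds in both classes: {sorted(overlap)}")
        if self.active_range[1] >= self.inactive_range[0]:
            raise ClassDefinitionError("class IC50 ranges overlap")


@dataclass
class ComparisonResult:
    metric_name: str
    mean_A: float
    mean_I: float
    n_A: int
    n_I: int
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def load_activity_table(tsv: str) -> list[ActivityRecord]:
    """Parse an activity TSV (text content) into records.

    Missing cells use the ``nd`` convention; non-positive or non-numeric
    IC50 cells raise with the offending line number.
    """
    reader = csv.DictReader(io.StringIO(tsv), delimiter="\t")
    if reader.fieldnames is None:
        return []
    required = {"compound_id", "series"}
    missing = required - set(reader.fieldnames)
    if missing:
        raise ActivityTableError(f"missing required columns: {sorted(missing)}")
    records: list[ActivityRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        cid = (row.get("compound_id") or "").strip()
        if not cid:
            raise ActivityTableError(f"line {lineno}: empty compound_id")
        if cid in seen:
            raise ActivityTableError(f"line {lineno}: duplicate compound_id {cid!r}")
        seen.add(cid)
        kwargs: dict = {"compound_id": cid, "series": (row.get("series") or "").strip()}
        for col, attr in _TSV_COLUMNS.items():
            raw = (row.get(col) or "").strip()
            if raw.lower() in _MISSING_TOKENS:
                kwargs[attr] = None
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise ActivityTableError(
                    f"line {lineno}: non-numeric value {raw!r} in column {col}"
                ) from exc
            kwargs[attr] = value
        try:
            records.append(ActivityRecord(**kwargs))
        except ActivityTableError as exc:
            raise ActivityTableError(f"line {lineno}: {exc}") from exc
    return records


def load_packaged_activity() -> list[ActivityRecord]:
    """The activity table shipped with the package."""
    text = (
        importlib.resources.files("ligpocket")
        .joinpath("data/activity.tsv")
        .read_text(encoding="utf-8")
    )
    return load_activity_table(text)


def pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar); input is nM."""
    if ic50_nM is None or ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return -math.log10(ic50_nM * 1e-9)


def series_extreme(
    records: list[ActivityRecord],
    series: str,
    assay: str = "pde4b1",
    which: str = "min",
) -> tuple[str, float]:
    """The extreme assay value over a series, with its compound id."""
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    pool = [
        (r.compound_id, r.assay(assay))
        for r in records
        if r.series == str(series) and r.assay(assay) is not None
    ]
    if not pool:
        raise ValueError(f"no records in series {series!r} with assay {assay!r}")
    pick = min if which == "min" else max
    cid, value = pick(pool, key=lambda t: t[1])
    return cid, value


def filter_potent(
    records: list[ActivityRecord],
    assay: str = "pde4b1",
    threshold_nM: float = 100.0,
) -> list[ActivityRecord]:
    """Records whose assay value is <= threshold (inclusive); records
    lacking the assay are dropped."""
    return [
        r for r in records
        if r.assay(assay) is not None and r.assay(assay) <= threshold_nM
    ]


def selectivity_ratio(record: ActivityRecord, assay_num: str, assay_den: str) -> float:
    num = record.assay(assay_num)
    den = record.assay(assay_den)
    if num is None or den is None:
        raise ValueError(
            f"{record.compound_id}: both assays required "
            f"({assay_num}={num}, {assay_den}={den})"
        )
    return num / den


def mned_fold(record: ActivityRecord, reference: ActivityRecord) -> float:
    """Maximal-not-emetic-dose fold ratio versus the reference compound."""
    if record.mned_ferret is None or reference.mned_ferret is None:
        raise ValueError("both records need an MNED value")
    return record.mned_ferret / reference.mned_ferret


def assign_modeling_class(
    record: ActivityRecord,
    definition: ClassDefinition | None = None,
    use_range_fallback: bool = False,
) -> str:
    """Class A (active) / I (low-active) / 'unassigned'.

    The explicit membership lists are authoritative. With
    ``use_range_fallback`` enabled, compounds outside both lists are
    classified by whether their potency lies inside the class IC50 ranges;
    this is off by default because the published class memberships are an
    explicit enumeration, not a potency cut.
    """
    definition = definition or ClassDefinition()
    if record.compound_id in definition.active_members:
        return "A"
    if record.compound_id in definition.inactive_members:
        return "I"
    value = record.ic50_pde4b1
    if use_range_fallback and value is not None:
        lo, hi = definition.active_range
        if lo <= value <= hi:
            return "A"
        lo, hi = definition.inactive_range
        if lo <= value <= hi:
            return "I"
    return "unassigned"


def compare_classes(
    values_A,
    values_I,
    alpha: float = 0.05,
    metric_name: str = "",
    method: str = "welch",
) -> ComparisonResult:
    """Two-sided two-sample comparison of class metrics.

    Default is Welch's unequal-variance t-test; ``method='ranksum'``
    switches to the Mann-Whitney U test.
    """
    values_A = np.asarray(list(values_A), dtype=float)
    values_I = np.asarray(list(values_I), dtype=float)
    if len(values_A) < 2 or len(values_I) < 2:
        raise ValueError("need at least 2 values per class")
    if method == "welch":
        with warnings.catch_warnings():
            # constant equal samples trigger a precision warning; that case
            # is handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(values_A, values_I, equal_var=False)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):  # both samples constant and equal
            statistic, p_value = 0.0, 1.0
    elif method == "ranksum":
        res = stats.mannwhitneyu(values_A, values_I, alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        metric_name=metric_name,
        mean_A=float(np.mean(values_A)),
        mean_I=float(np.mean(values_I)),
        n_A=len(values_A),
        n_I=len(values_I),
        statistic=statistic,
        p_value=p_value,
        alpha=alpha,
    )
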