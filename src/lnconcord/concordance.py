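"""Radiology-pathology concordance statistics.

CT finds a different set of nodes than the pathologist harvests (in the
motivating cohort, 1079 CT-visible vs 1809 harvested nodes), so node-to-node
identity across the two modalities is never assumed.  The matching unit is
the nodal STATION: counts of CT nodes / suspicious nodes and harvested /
metastatic nodes are aggregated per station and compared there.  Each
patient-station falls into one of four concordance categories:

* positive        -- suspicious on CT and metastatic on histology;
* negative        -- neither suspicious nor metastatic;
* false_positive  -- suspicious on CT, nothing metastatic harvested;
* false_negative  -- metastatic on histology, nothing suspicious on CT.

Two summary ratios are computed.  The suspicious-to-positive ratio (SPR) is
the count of CT-suspicious nodes divided by the count of histologically
metastatic nodes, pooled over a band, a tumor site or the whole cohort
(ratio of sums, never a mean of ratios); it is reported as undefined when no
metastatic node exists.  The lymph-node ratio (LNR) is metastatic over
harvested nodes.

The node-level 2x2 (suspicious vs metastatic) requires a histology label
for each CT node; since individual CT nodes carry none, a CT node counts as
metastasis-exposed iff its own patient's station contains at least one
metastatic harvested node.  This station-context reconstruction is a
modelling choice, flagged in the package documentation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IntegrityError
from .station_map import DistanceBand, StationRegistry, TumorSite, parse_site
from .suspicion import PATTERN_ORDER, EnhancementPattern, validate_pattern

# --------------------------------------------------------------------------
# categories and scalar ratios
# --------------------------------------------------------------------------


class ConcordanceCategory(enum.Enum):
    positive = "positive"
    negative = "negative"
    false_positive = "false_positive"
    false_negative = "false_negative"

    def __str__(self) -> str:
        return self.value


def _check_count(name: str, value: int) -> int:
    if isinstance(value, bool) or (not isinstance(value, (int, np.integer))):
        if isinstance(value, float) and float(value).is_integer():
            value = int(value)
        else:
            raise DomainError(f"{name} must be an integer count, got {value!r}")
    if value < 0:
        raise DomainError(f"{name} must be non-negative, got {value}")
    return int(value)


def correlation_category(n_suspicious: int, n_positive: int) -> ConcordanceCategory:
    """Assign the four-way concordance category from per-station counts."""
    s = _check_count("n_suspicious", n_suspicious)
    p = _check_count("n_positive", n_positive)
    if s > 0 and p > 0:
        return ConcordanceCategory.positive
    if s == 0 and p == 0:
        return ConcordanceCategory.negative
    if s > 0:
        return ConcordanceCategory.false_positive
    return ConcordanceCategory.false_negative


def compute_spr(n_suspicious: int, n_positive: int) -> Optional[float]:
    """Suspicious-to-positive ratio; None (undefined) when nothing is positive.

    Never returns infinity: a suspicious count with zero metastatic nodes is
    an undefined ratio, not an infinite one.
    """
    s = _check_count("n_suspicious", n_suspicious)
    p = _check_count("n_positive", n_positive)
    if p == 0:
        return None
    return s / p


def compute_lnr(n_positive: int, n_harvested: int) -> float:
    """Lymph-node ratio: metastatic / harvested nodes, in [0, 1]."""
    p = _check_count("n_positive", n_positive)
    h = _check_count("n_harvested", n_harvested)
    if h == 0:
        raise DomainError("LNR undefined with zero harvested nodes")
    if p > h:
        raise DomainError(f"positive nodes ({p}) exceed harvested nodes ({h})")
    return p / h


# --------------------------------------------------------------------------
# the 2x2 table and its statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = exposure (suspicion), columns = outcome (metastasis).

    Layout::

                    outcome+   outcome-
        exposed        a          b
        unexposed      c          d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.n == 0:
            raise DomainError("2x2 table must have a positive grand total")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray       # 2x2 expected counts under independence
    contributions: np.ndarray  # per-cell (O-E)^2/E terms
    yates: bool


def pearson_chi_square(table: ContingencyTable2x2, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 table.

    Plain Pearson by default (no continuity correction); the Yates
    correction is available behind the flag.  Expected cells are
    row_total*col_total/n and the statistic is the sum of the per-cell
    (O-E)^2/E contributions; p is the upper tail of chi-square with 1 df.

    Raises DomainError when any marginal is zero (statistic undefined).
    """
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DomainError("chi-square undefined: a marginal total is zero")
    expected = np.outer(rows, cols) / table.n
    delta = np.abs(obs - expected)
    if yates:
        delta = np.maximum(delta - 0.5, 0.0)
    contributions = delta**2 / expected
    statistic = float(contributions.sum())
    p_value = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic, 1, p_value, expected, contributions, yates)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool
    fisher_p: Optional[float] = None


def odds_ratio(
    table: ContingencyTable2x2,
    zero_cell_correction: bool = True,
    fisher: bool = False,
    confidence: float = 0.95,
) -> OddsRatioResult:
    """Odds ratio (ad)/(bc) with a Woolf (log-normal) confidence interval.

    When any cell is zero and ``zero_cell_correction`` is on, 0.5 is added
    to every cell (Haldane-Anscombe) before everything else; otherwise a
    zero cell raises DomainError.  The two-sided p comes from the Wald z of
    ln OR; a Fisher exact p is attached when ``fisher`` is set.
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    corrected = False
    if (cells == 0).any():
        if not zero_cell_correction:
            raise DomainError(
                "odds ratio undefined with a zero cell "
                "(enable the Haldane-Anscombe correction)"
            )
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p_value = float(2 * stats.norm.sf(abs(log_or) / se))
    fisher_p = None
    if fisher:
        fisher_p = float(stats.fisher_exact(table.as_array().astype(int))[1])
    return OddsRatioResult(math.exp(log_or), ci_low, ci_high, p_value, corrected, fisher_p)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV; None marks an undefined metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """Diagnostic accuracy of exposure (suspicion) against outcome (metastasis).

    sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d);
    each is None when its denominator is zero.
    """
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=ratio(table.a, table.a + table.c),
        specificity=ratio(table.d, table.b + table.d),
        ppv=ratio(table.a, table.a + table.b),
        npv=ratio(table.d, table.c + table.d),
    )


# --------------------------------------------------------------------------
# station-level matching
# --------------------------------------------------------------------------

CT_COLUMNS = (
    "node_id", "patient_id", "station_code", "short_axis_mm",
    "roundness", "heterogeneous_density", "irregular_border",
    "pattern", "suspicious",
)
HISTO_COLUMNS = ("node_id", "patient_id", "station_code", "metastatic")
PATIENT_COLUMNS = ("patient_id", "sex", "age", "tumor_site")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise IntegrityError(f"{what} table is missing columns {missing}")


def _check_stations(df: pd.DataFrame, registry: StationRegistry, what: str) -> None:
    codes = set(df["station_code"].astype(str))
    unknown = sorted(c for c in codes if c not in registry)
    if unknown:
        raise DomainError(f"{what} table has unresolvable station codes: {unknown}")


def station_concordance(
    ct_nodes: pd.DataFrame,
    histo_nodes: pd.DataFrame,
    registry: StationRegistry,
    by_patient: bool = False,
) -> pd.DataFrame:
    """Aggregate CT and histology counts per station and categorise each.

    One output row per station (or per patient-station with ``by_patient``)
    appearing in either table, with columns ``n_ct``, ``n_suspicious``,
    ``n_harvested``, ``n_positive``, ``band``, ``category`` and ``spr``.
    Counts are aggregated at station level; node identity across the two
    modalities is not assumed.
    """
    _require_columns(ct_nodes, ("patient_id", "station_code", "suspicious"), "CT node")
    _require_columns(histo_nodes, ("patient_id", "station_code", "metastatic"), "histology node")
    _check_stations(ct_nodes, registry, "CT node")
    _check_stations(histo_nodes, registry, "histology node")

    keys = ["patient_id", "station_code"] if by_patient else ["station_code"]
    ct = (
        ct_nodes.assign(station_code=ct_nodes["station_code"].astype(str))
        .groupby(keys, sort=True)
        .agg(n_ct=("suspicious", "size"), n_suspicious=("suspicious", "sum"))
    )
    hi = (
        histo_nodes.assign(station_code=histo_nodes["station_code"].astype(str))
        .groupby(keys, sort=True)
        .agg(n_harvested=("metastatic", "size"), n_positive=("metastatic", "sum"))
    )
    merged = ct.join(hi, how="outer").fillna(0).astype(int).reset_index()
    merged["band"] = [str(registry.get(c).band) for c in merged["station_code"]]
    merged["category"] = [
        str(correlation_category(s, p))
        for s, p in zip(merged["n_suspicious"], merged["n_positive"])
    ]
    merged["spr"] = [
        compute_spr(s, p)
        for s, p in zip(merged["n_suspicious"], merged["n_positive"])
    ]
    return merged


def attach_station_outcome(
    ct_nodes: pd.DataFrame, histo_nodes: pd.DataFrame
) -> pd.DataFrame:
    """Label each CT node with its patient-station metastasis context.

    Adds a boolean ``metastatic`` column: True iff the same patient's same
    station contains at least one metastatic harvested node.  This is the
    reconstruction that lets CT nodes carry a histology outcome at all.
    """
    _require_columns(ct_nodes, ("patient_id", "station_code"), "CT node")
    _require_columns(histo_nodes, ("patient_id", "station_code", "metastatic"), "histology node")
    met = (
        histo_nodes.groupby(["patient_id", "station_code"])["metastatic"]
        .any()
        .rename("metastatic")
    )
    out = ct_nodes.drop(columns=["metastatic"], errors="ignore").join(
        met, on=["patient_id", "station_code"]
    )
    out["metastatic"] = out["metastatic"].eq(True)  # NaN (no harvest) -> False
    return out


# --------------------------------------------------------------------------
# pattern association (one-vs-rest odds ratios)
# --------------------------------------------------------------------------


def pattern_association(
    nodes_with_outcome: Union[pd.DataFrame, Iterable[tuple]],
    zero_cell_correction: bool = True,
) -> dict[EnhancementPattern, OddsRatioResult]:
    """Per-pattern odds of metastasis, each pattern against all others.

    Input is a DataFrame with ``pattern`` and ``metastatic`` columns (or an
    iterable of such pairs).  For each pattern k present the 2x2
    (pattern k vs rest) x (metastatic vs not) is built and the odds ratio
    of metastasis given pattern k is returned.  A single-pattern input is a
    degenerate comparison and raises DomainError.
    """
    if not isinstance(nodes_with_outcome, pd.DataFrame):
        nodes_with_outcome = pd.DataFrame(
            list(nodes_with_outcome), columns=["pattern", "metastatic"]
        )
    if nodes_with_outcome.empty:
        raise DomainError("pattern association needs at least one node")
    df = nodes_with_outcome.copy()
    df["pattern"] = [validate_pattern(p) for p in df["pattern"]]
    df["metastatic"] = df["metastatic"].astype(bool)
    present = set(df["pattern"])
    if len(present) < 2:
        raise DomainError(
            "pattern association is degenerate: all nodes share one pattern"
        )
    results: dict[EnhancementPattern, OddsRatioResult] = {}
    for pat in PATTERN_ORDER:
        if pat not in present:
            continue
        is_k = df["pattern"] == pat
        a = int((is_k & df["metastatic"]).sum())
        b = int((is_k & ~df["metastatic"]).sum())
        c = int((~is_k & df["metastatic"]).sum())
        d = int((~is_k & ~df["metastatic"]).sum())
        results[pat] = odds_ratio(
            ContingencyTable2x2(a, b, c, d), zero_cell_correction=zero_cell_correction
        )
    return results


# --------------------------------------------------------------------------
# cohort summary
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level concordance summary.

    SPRs are ratios of pooled counts (None where undefined); the node-level
    2x2 uses the station-context outcome label; patient-level test
    positivity is >=1 suspicious node, disease positivity >=1 metastatic
    node.
    """

    n_patients: int
    n_ct_nodes: int
    n_suspicious: int
    n_harvested: int
    n_positive: int
    overall_lnr: float
    overall_spr: Optional[float]
    suspicious_fraction: float
    node_metastasis_rate: float
    patient_positive_fraction: float
    band_spr: dict[str, Optional[float]]
    site_spr: dict[str, Optional[float]]
    category_counts: dict[str, int]
    node_table: ContingencyTable2x2
    node_metrics: DiagnosticMetrics
    patient_table: Optional[ContingencyTable2x2]
    patient_metrics: Optional[DiagnosticMetrics]


def _pooled_spr(df: pd.DataFrame) -> Optional[float]:
    return compute_spr(int(df["n_suspicious"].sum()), int(df["n_positive"].sum()))


def validate_cohort(
    patients: pd.DataFrame,
    ct_nodes: pd.DataFrame,
    histo_nodes: pd.DataFrame,
    registry: StationRegistry,
) -> None:
    """Referential-integrity checks across the three cohort tables."""
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    _require_columns(ct_nodes, ("node_id", "patient_id", "station_code", "suspicious"), "CT node")
    _require_columns(histo_nodes, HISTO_COLUMNS, "histology node")
    known = set(patients["patient_id"])
    for what, df in (("CT node", ct_nodes), ("histology node", histo_nodes)):
        orphans = sorted(set(df["patient_id"]) - known)
        if orphans:
            raise IntegrityError(
                f"{what} table references unknown patient ids: {orphans[:20]}"
            )
    _check_stations(ct_nodes, registry, "CT node")
    _check_stations(histo_nodes, registry, "histology node")
    for s in patients["tumor_site"]:
        parse_site(s)


def cohort_summary(
    patients: pd.DataFrame,
    ct_nodes: pd.DataFrame,
    histo_nodes: pd.DataFrame,
    registry: StationRegistry,
) -> CohortSummary:
    """Compute the full concordance summary for one cohort."""
    validate_cohort(patients, ct_nodes, histo_nodes, registry)

    per_station = station_concordance(ct_nodes, histo_nodes, registry, by_patient=True)
    site_of = patients.set_index("patient_id")["tumor_site"].astype(str)

    n_ct = len(ct_nodes)
    n_susp = int(ct_nodes["suspicious"].sum())
    n_harv = len(histo_nodes)
    n_pos = int(histo_nodes["metastatic"].sum())

    band_spr = {
        str(band): _pooled_spr(per_station[per_station["band"] == str(band)])
        for band in DistanceBand
    }
    per_station_sites = per_station["patient_id"].map(site_of)
    site_spr = {
        str(site): _pooled_spr(per_station[per_station_sites == str(site)])
        for site in TumorSite
    }
    category_counts = {str(c): 0 for c in ConcordanceCategory}
    category_counts.update(per_station["category"].value_counts().to_dict())

    labelled = attach_station_outcome(ct_nodes, histo_nodes)
    susp = labelled["suspicious"].astype(bool)
    met = labelled["metastatic"]
    node_table = ContingencyTable2x2(
        int((susp & met).sum()),
        int((susp & ~met).sum()),
        int((~susp & met).sum()),
        int((~susp & ~met).sum()),
    )

    test_pos = ct_nodes.groupby("patient_id")["suspicious"].any()
    disease_pos = histo_nodes.groupby("patient_id")["metastatic"].any()
    per_patient = pd.DataFrame({"patient_id": patients["patient_id"]}).set_index("patient_id")
    per_patient["test_pos"] = test_pos.reindex(per_patient.index).fillna(False)
    per_patient["disease_pos"] = disease_pos.reindex(per_patient.index).fillna(False)
    tp = per_patient["test_pos"]
    dp = per_patient["disease_pos"]
    try:
        patient_table: Optional[ContingencyTable2x2] = ContingencyTable2x2(
            int((tp & dp).sum()), int((tp & ~dp).sum()),
            int((~tp & dp).sum()), int((~tp & ~dp).sum()),
        )
        patient_metrics: Optional[DiagnosticMetrics] = diagnostic_metrics(patient_table)
    except DomainError:
        patient_table = None
        patient_metrics = None

    return CohortSummary(
        n_patients=len(patients),
        n_ct_nodes=n_ct,
        n_suspicious=n_susp,
        n_harvested=n_harv,
        n_positive=n_pos,
        overall_lnr=compute_lnr(n_pos, n_harv),
        overall_spr=compute_spr(n_susp, n_pos),
        suspicious_fraction=n_susp / n_ct if n_ct else 0.0,
        node_metastasis_rate=n_pos / n_harv if n_harv else 0.0,
        patient_positive_fraction=float(dp.mean()) if len(per_patient) else 0.0,
        band_spr=band_spr,
        site_spr=site_spr,
        category_counts=category_counts,
        node_table=node_table,
        node_metrics=diagnostic_metrics(node_table),
        patient_table=patient_table,
        patient_metrics=patient_metrics,
    )
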