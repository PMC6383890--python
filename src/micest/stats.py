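"""ROI outcome extraction, MRS quality control, creatine normalization and
paired group statistics.

Study conventions implemented here: outcome values are ROI averages of the
MTR asymmetry map; metabolite concentrations pass quality control only when
the spectrum linewidth does not exceed 25 Hz (whole spectrum excluded
otherwise) and the metabolite's Cramér-Rao bound is below 10% (single
metabolite excluded otherwise); concentrations are expressed as ratios to
total creatine (creatine + phosphocreatine); paired LPS-vs-vehicle outcomes
are compared with a paired t-test and nonparametric Wilcoxon tests, and
described as median (interquartile range).

The nonparametric test named in the study protocol is a "Wilcoxon rank sum
test" applied to paired data; the paired-design analogue is the Wilcoxon
signed-rank test, which is computed here as the primary nonparametric
p-value, with the two-sample rank-sum p-value reported alongside, both
labeled. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConfigurationError, ImageGeometry, RoiSpec

__all__ = [
    "roi_mean",
    "mrs_qc_and_ratio",
    "PairedOutcome",
    "PairedComparison",
    "paired_compare",
    "CRLB_MAX_PERCENT",
    "LINEWIDTH_MAX_HZ",
]

#: metabolite inclusion gate: Cramér-Rao bound strictly below 10 %SD
CRLB_MAX_PERCENT = 10.0
#: spectrum inclusion gate: linewidth must not exceed 25 Hz
LINEWIDTH_MAX_HZ = 25.0


def roi_mean(
    value_map: np.ndarray,
    roi: RoiSpec,
    geometry: ImageGeometry,
    valid: np.ndarray | None = None,
    statistic: str = "mean",
) -> float:
    """Average of a per-voxel map over the ROI's whole-pixel window.

    Only valid (finite, unmasked) voxels contribute; NaN is returned, with no
    exception, when the ROI holds none. ``statistic`` may be "median" for the
    robust variant.
    """
    rows, cols = roi.to_slices(geometry)
    block = value_map[rows, cols]
    ok = np.isfinite(block)
    if valid is not None:
        ok &= valid[rows, cols]
    if not np.any(ok):
        return float("nan")
    agg = np.mean if statistic == "mean" else np.median
    return float(agg(block[ok]))


def mrs_qc_and_ratio(
    table: pd.DataFrame,
    crlb_max: float = CRLB_MAX_PERCENT,
    linewidth_max: float = LINEWIDTH_MAX_HZ,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply MRS quality gates and compute metabolite / total-creatine ratios.

    ``table`` needs columns subject, side, metabolite, concentration,
    crlb_percent, linewidth_hz. Spectra (subject, side) whose linewidth
    exceeds ``linewidth_max`` are dropped whole; metabolites at or above
    ``crlb_max`` %SD are dropped individually. Total creatine is Cr + PCr and
    both must survive QC, else the spectrum's ratios are undefined and an
    error is raised for that spectrum (recorded as an exclusion instead when
    other spectra remain).

    Returns ``(ratios, exclusions)``: ratios has columns subject, side,
    metabolite, ratio_to_tcr; exclusions has subject, side, metabolite (empty
    for whole-spectrum exclusions) and reason codes.
    """
    required = {"subject", "side", "metabolite", "concentration",
                "crlb_percent", "linewidth_hz"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"metabolite table missing {required - set(table.columns)}")
    if not {"Cr", "PCr"}.issubset(set(table["metabolite"])):
        raise ConfigurationError("creatine rows (Cr, PCr) required for tCr ratios")

    excl = []
    out = []
    for (subj, side), spec_rows in table.groupby(["subject", "side"], sort=True):
        lw = float(spec_rows["linewidth_hz"].iloc[0])
        if lw > linewidth_max:
            excl.append({"subject": subj, "side": side, "metabolite": "",
                         "reason": "linewidth_exceeded", "value": lw})
            continue
        ok = spec_rows[spec_rows["crlb_percent"] < crlb_max]
        for _, r in spec_rows[spec_rows["crlb_percent"] >= crlb_max].iterrows():
            excl.append({"subject": subj, "side": side,
                         "metabolite": r["metabolite"],
                         "reason": "crlb_exceeded", "value": r["crlb_percent"]})
        cr = ok[ok["metabolite"] == "Cr"]["concentration"]
        pcr = ok[ok["metabolite"] == "PCr"]["concentration"]
        if cr.empty or pcr.empty:
            excl.append({"subject": subj, "side": side, "metabolite": "",
                         "reason": "tcr_unmeasurable", "value": np.nan})
            continue
        tcr = float(cr.iloc[0]) + float(pcr.iloc[0])
        for _, r in ok.iterrows():
            if r["metabolite"] in ("Cr", "PCr"):
                continue
            out.append({"subject": subj, "side": side,
                        "metabolite": r["metabolite"],
                        "ratio_to_tcr": r["concentration"] / tcr})
    ratios = pd.DataFrame(out, columns=["subject", "side", "metabolite", "ratio_to_tcr"])
    exclusions = pd.DataFrame(excl, columns=["subject", "side", "metabolite", "reason", "value"])
    if ratios.empty and exclusions.empty:
        raise ConfigurationError("empty metabolite table")
    return ratios, exclusions


@dataclass
class PairedOutcome:
    """Complete per-subject (LPS, vehicle) pairs for one outcome measure."""

    measure: str
    subjects: list
    lps: np.ndarray
    pbs: np.ndarray

    def __post_init__(self) -> None:
        self.lps = np.asarray(self.lps, dtype=float)
        self.pbs = np.asarray(self.pbs, dtype=float)
        if not (len(self.subjects) == self.lps.size == self.pbs.size):
            raise ConfigurationError("pairs must be complete per subject")
        keep = np.isfinite(self.lps) & np.isfinite(self.pbs)
        if not np.all(keep):
            self.subjects = [s for s, k in zip(self.subjects, keep) if k]
            self.lps = self.lps[keep]
            self.pbs = self.pbs[keep]

    @property
    def n(self) -> int:
        return self.lps.size


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q25), float(q75)


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired LPS-vs-vehicle comparison."""

    measure: str
    n: int
    lps_median: float
    lps_iqr: tuple[float, float]
    pbs_median: float
    pbs_iqr: tuple[float, float]
    median_difference: float
    p_ttest: float
    p_wilcoxon_signed_rank: float
    p_rank_sum: float
    tests_computed: bool

    def summary_row(self) -> dict:
        return {
            "measure": self.measure,
            "n": self.n,
            "LPS median (IQR)": f"{self.lps_median:.3g} ({self.lps_iqr[0]:.3g}-{self.lps_iqr[1]:.3g})",
            "PBS median (IQR)": f"{self.pbs_median:.3g} ({self.pbs_iqr[0]:.3g}-{self.pbs_iqr[1]:.3g})",
            "p (paired t)": self.p_ttest,
            "p (signed-rank)": self.p_wilcoxon_signed_rank,
            "p (rank-sum)": self.p_rank_sum,
        }


def paired_compare(outcome: PairedOutcome, min_n: int = 3) -> PairedComparison:
    """Paired t-test plus Wilcoxon tests on LPS-vs-vehicle pairs.

    With fewer than ``min_n`` complete pairs only descriptives are reported
    and the test p-values are NaN (``tests_computed`` False). All-zero
    differences make the t statistic undefined; p is reported as 1 (no
    evidence against the null).
    """
    lps, pbs = outcome.lps, outcome.pbs
    if outcome.n == 0:
        raise ConfigurationError("no complete pairs to compare")
    l50, l25, l75 = _median_iqr(lps)
    p50, p25, p75 = _median_iqr(pbs)
    diff_median = float(np.median(lps - pbs))
    if outcome.n < min_n:
        return PairedComparison(outcome.measure, outcome.n, l50, (l25, l75),
                                p50, (p25, p75), diff_median,
                                float("nan"), float("nan"), float("nan"), False)
    d = lps - pbs
    if np.allclose(d, 0.0):
        p_t, p_w = 1.0, 1.0
    else:
        p_t = float(sps.ttest_rel(lps, pbs).pvalue)
        if np.isnan(p_t):  # zero-variance nonzero differences
            p_t = 0.0
        try:
            p_w = float(sps.wilcoxon(lps, pbs, zero_method="wilcox").pvalue)
        except ValueError:
            p_w = 1.0
    p_rs = float(sps.ranksums(lps, pbs).pvalue)
    return PairedComparison(outcome.measure, outcome.n, l50, (l25, l75),
                            p50, (p25, p75), diff_median, p_t, p_w, p_rs, True)
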