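"""Treatment-response classification and cohort statistics.

Histopathological response follows the Rubbia-Brandt tumour-regression grade
(1 = no residual tumour ... 5 = no regression): grades 1-2 are a major
response, grade 3 a partial response, grades 4-5 no response.  Radiological
response follows RECIST 1.1 on target-lesion diameters (-30% partial
response, +20% progressive disease, otherwise stable).  On cohort tables the
module provides the statistical toolkit such studies use: concordance of the two
response assessments, per-frequency Spearman correlations of the dispersion
proxies against grade or response, Kruskal-Wallis group comparisons with
median/IQR reporting, and rank-based ROC AUC with a Youden-optimal cutpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidGradeError, InvalidInputError

RESPONSE_CLASSES = ("major", "partial", "none")
#: Ordinal coding for response used in correlations: none < partial < major.
RESPONSE_ORDINAL = {"none": 0, "partial": 1, "major": 2}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed clinical tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_histo_response(grade: int) -> str:
    """Map a Rubbia-Brandt grade to major / partial / none."""
    if grade not in (1, 2, 3, 4, 5):
        raise InvalidGradeError(f"Rubbia-Brandt grade must be 1-5, got {grade}")
    if grade <= 2:
        return "major"
    if grade == 3:
        return "partial"
    return "none"


def classify_recist(baseline_diam: float, followup_diam: float) -> str:
    """RECIST 1.1 on a single target lesion: rPR / rSD / rPD.

    Diameter change of at least -30% is a radiological partial response,
    at least +20% progressive disease, anything between stable disease.
    Both thresholds are inclusive ("at least").
    """
    if baseline_diam <= 0 or followup_diam <= 0:
        raise InvalidInputError("diameters must be positive")
    delta_pct = (followup_diam - baseline_diam) / baseline_diam * 100.0
    if delta_pct <= -30.0:
        return "rPR"
    if delta_pct >= 20.0:
        return "rPD"
    return "rSD"


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement of radiological (rPR) vs pathological (major) response.

    Cells hold counts; ``percentages`` the same cells as percent of total,
    rounded half-up to one decimal.  "Presence" of pathological response
    means histological major response; of radiological response, rPR.
    """

    both_absent: int
    patho_only: int       # pathological presence, radiological absence
    radio_only: int       # radiological presence, pathological absence
    both_present: int

    @property
    def n(self) -> int:
        return self.both_absent + self.patho_only + self.radio_only + self.both_present

    @property
    def concordant(self) -> int:
        return self.both_absent + self.both_present

    @property
    def discordant(self) -> int:
        return self.patho_only + self.radio_only

    def percentages(self) -> dict[str, float]:
        n = self.n
        if n == 0:
            raise InvalidInputError("empty concordance table")
        pct = lambda c: round_half_up(c / n * 100.0, 1)
        return {
            "both_absent": pct(self.both_absent),
            "patho_only": pct(self.patho_only),
            "radio_only": pct(self.radio_only),
            "both_present": pct(self.both_present),
            "concordant": pct(self.concordant),
            "discordant": pct(self.discordant),
        }


def concordance(histo_responses: Sequence[str],
                recist_classes: Sequence[str]) -> ConcordanceTable:
    """Build the 2x2 concordance table from paired assessments.

    Records with ``recist == 'missing'`` are dropped (clinically unavailable
    imaging); the remaining pairs must be non-empty.
    """
    pairs = [(h, r) for h, r in zip(histo_responses, recist_classes, strict=True)
             if r != "missing"]
    if not pairs:
        raise InvalidInputError("no records with both assessments")
    cells = {"aa": 0, "pa": 0, "ra": 0, "pp": 0}
    for h, r in pairs:
        patho = h == "major"
        radio = r == "rPR"
        if patho and radio:
            cells["pp"] += 1
        elif patho:
            cells["pa"] += 1
        elif radio:
            cells["ra"] += 1
        else:
            cells["aa"] += 1
    return ConcordanceTable(both_absent=cells["aa"], patho_only=cells["pa"],
                            radio_only=cells["ra"], both_present=cells["pp"])


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str
    n: int
    f: float | None = None
    defined: bool = True


def spearman(values: Sequence[float], classifier: Sequence[float],
             f: float | None = None) -> CorrelationResult:
    """Spearman rank correlation; constant input is flagged, not raised."""
    values = np.asarray(values, dtype=float)
    classifier = np.asarray(classifier, dtype=float)
    if values.size != classifier.size:
        raise InvalidInputError("length mismatch")
    if values.size < 4:
        raise InvalidInputError("need >= 4 paired observations")
    if np.ptp(values) == 0 or np.ptp(classifier) == 0:
        return CorrelationResult(coefficient=math.nan, p_value=math.nan,
                                 method="spearman", n=values.size, f=f,
                                 defined=False)
    rho, p = sps.spearmanr(values, classifier)
    return CorrelationResult(coefficient=float(rho), p_value=float(p),
                             method="spearman", n=values.size, f=f)


def correlate_by_frequency(records: Sequence["object"], value: str = "c",
                           classifier: str = "grade") -> list[CorrelationResult]:
    """Per-frequency Spearman correlation of c or a against an ordinal label.

    ``records`` are cohort samples (see :mod:`cylmre.cohort`) carrying a
    ``dispersion`` mapping frequency -> (c, a), a ``rubbia_brandt`` grade and
    a ``histo_response`` class.  The classifier is coded 1-5 for grade and
    none=0 < partial=1 < major=2 for response.  Frequencies with fewer than
    4 valid records are skipped.
    """
    if value not in ("c", "a"):
        raise InvalidInputError("value must be 'c' or 'a'")
    if classifier not in ("grade", "response"):
        raise InvalidInputError("classifier must be 'grade' or 'response'")
    freqs = sorted({f for rec in records for f in rec.dispersion})
    out: list[CorrelationResult] = []
    comp = 0 if value == "c" else 1
    for f in freqs:
        vals, labs = [], []
        for rec in records:
            if f not in rec.dispersion:
                continue
            v = rec.dispersion[f][comp]
            if not math.isfinite(v):
                continue
            vals.append(v)
            labs.append(rec.rubbia_brandt if classifier == "grade"
                        else RESPONSE_ORDINAL[rec.histo_response])
        if len(vals) < 4:
            continue
        out.append(spearman(vals, labs, f=f))
    return out


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupComparison:
    groups: dict[str, GroupSummary]
    kruskal_p: float | None
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False


def compare_groups(values_by_group: dict[str, Sequence[float]],
                   fdr: bool = False) -> GroupComparison:
    """Median/IQR per group, Kruskal-Wallis omnibus, pairwise rank-sum tests.

    Quartiles use linear interpolation (type 7).  Empty groups are dropped.
    Groups too small for rank tests (any n < 2, or fewer than 2 groups)
    yield a degenerate result without p-values.  With ``fdr=True`` the
    pairwise Mann-Whitney p-values are Benjamini-Hochberg adjusted.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()
              if len(v) > 0}
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 non-empty groups")
    summaries = {
        k: GroupSummary(n=v.size, median=float(np.median(v)),
                        q1=float(np.quantile(v, 0.25)),
                        q3=float(np.quantile(v, 0.75)))
        for k, v in groups.items()
    }
    if any(v.size < 2 for v in groups.values()):
        return GroupComparison(groups=summaries, kruskal_p=None, degenerate=True)
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        # identical data in every group: no evidence of difference
        return GroupComparison(groups=summaries, kruskal_p=1.0)
    _, kw_p = sps.kruskal(*groups.values())
    names = list(groups)
    pairs = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            if np.ptp(np.concatenate([groups[gi], groups[gj]])) == 0:
                pairs[(gi, gj)] = 1.0
            else:
                _, p = sps.mannwhitneyu(groups[gi], groups[gj],
                                        alternative="two-sided")
                pairs[(gi, gj)] = float(p)
    if fdr and pairs:
        keys = list(pairs)
        adj = _benjamini_hochberg(np.array([pairs[k] for k in keys]))
        pairs = dict(zip(keys, adj.tolist()))
    return GroupComparison(groups=summaries, kruskal_p=float(kw_p),
                           pairwise=pairs)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class AUCResult:
    auc: float
    cutpoint: float
    sensitivity: float
    specificity: float
    direction: str  # '>=': positives tend larger; '<=': positives tend smaller


def auc_cutpoint(values: Sequence[float], labels: Sequence[bool]) -> AUCResult:
    """Rank-based ROC AUC with the Youden-optimal cutpoint.

    AUC is the Mann-Whitney U statistic over n1*n0 with midranks (ties get
    half credit).  The reported AUC is oriented to be >= 0.5; ``direction``
    records whether positives lie above ('>=') or below ('<=') the cutpoint.
    Sensitivity and specificity are evaluated at the cutpoint maximizing
    Youden's J = sensitivity + specificity - 1; candidate cutpoints are
    midpoints between adjacent distinct values (plus outer sentinels).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.size != labels.size:
        raise InvalidInputError("length mismatch")
    n1 = int(labels.sum())
    n0 = int(values.size - n1)
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("both classes must be present")
    ranks = sps.rankdata(values)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    direction = ">="
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "<="
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = (-math.inf, cands[0], 0.0, 0.0)
    pos = values[labels]
    neg = values[~labels]
    for t in cands:
        if direction == ">=":
            sens = float(np.mean(pos >= t))
            spec = float(np.mean(neg < t))
        else:
            sens = float(np.mean(pos <= t))
            spec = float(np.mean(neg > t))
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, float(t), sens, spec)
    _, cut, sens, spec = best
    return AUCResult(auc=float(auc), cutpoint=cut, sensitivity=sens,
                     specificity=spec, direction=direction)


def cohort_proportions(histo_responses: Sequence[str]) -> dict[str, tuple[int, float]]:
    """Counts and percentages (half-up, one decimal) per response class."""
    responses = list(histo_responses)
    if not responses:
        raise InvalidInputError("need at least one record")
    n = len(responses)
    out = {}
    for cls in RESPONSE_CLASSES:
        cnt = responses.count(cls)
        out[cls] = (cnt, round_half_up(cnt / n * 100.0, 1))
    return out
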