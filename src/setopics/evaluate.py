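"""Repositioning evaluation of nearest-neighbor drug pairs.

Four questions are asked of the nearest-neighbor table:

1. how often does a drug share at least one indication with its nearest
   neighbor (recall), stratified by the query drug's indication count;
2. how does that compare with pairing each drug to a uniformly random other
   drug (Monte-Carlo null, with an exact analytic counterpart);
3. which boxed-warning drugs have a neighbor without a boxed warning that
   shares an indication (potential safer alternatives);
4. which ATC level-1 categories are enriched for successful pairs
   (two-sided Fisher's exact test per category).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import DrugRecord
from .distance import NearestNeighborTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairAssessment:
    drug_id: str
    neighbor_id: str
    shared_indications: frozenset[str]
    success: bool
    n_indications: int

    def __post_init__(self) -> None:
        if self.success != bool(self.shared_indications):
            raise ValueError("success must mirror a non-empty shared set")


@dataclass(frozen=True)
class RecallPoint:
    n_eligible: int
    n_success: int
    recall: float | None  # None when no drug is eligible at this threshold


@dataclass(frozen=True)
class RecallCurve:
    """Recall restricted to query drugs with at least m indications."""

    points: dict[int, RecallPoint]


@dataclass(frozen=True)
class NullEstimate:
    """Monte-Carlo mean (and spread) of the random-pairing recall curve."""

    mean: dict[int, float | None]
    std: dict[int, float | None]  # std of per-trial recalls
    n_trials: int
    seed: int


@dataclass(frozen=True)
class BwReplacementReport:
    replacements: list[tuple[str, str, frozenset[str]]]
    n_bw_drugs: int
    n_replaceable: int


@dataclass(frozen=True)
class AtcCategoryResult:
    category: str
    n_success_in: int
    n_fail_in: int
    n_success_out: int
    n_fail_out: int
    proportion: float
    p_value: float


def evaluate_pairs(
    nn: NearestNeighborTable, records: Sequence[DrugRecord]
) -> list[PairAssessment]:
    """Intersect each query drug's indications with its neighbor's."""
    by_id = {r.drug_id: r for r in records}
    out: list[PairAssessment] = []
    for drug_id, neighbor_id, _dist in nn.rows:
        if drug_id not in by_id or neighbor_id not in by_id:
            missing = drug_id if drug_id not in by_id else neighbor_id
            raise ValueError(f"no record for drug {missing!r}")
        rec = by_id[drug_id]
        shared = frozenset(rec.indications & by_id[neighbor_id].indications)
        out.append(
            PairAssessment(
                drug_id=drug_id,
                neighbor_id=neighbor_id,
                shared_indications=shared,
                success=bool(shared),
                n_indications=len(rec.indications),
            )
        )
    return out


def overall_recall(assessments: Sequence[PairAssessment]) -> float:
    if not assessments:
        raise ValueError("no assessments")
    return sum(a.success for a in assessments) / len(assessments)


def recall_curve(assessments: Sequence[PairAssessment], max_m: int) -> RecallCurve:
    """Recall over query drugs with >= m indications, for m = 1..max_m.

    Thresholds where no drug is eligible yield ``recall=None`` rather than 0.
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    points: dict[int, RecallPoint] = {}
    for m in range(1, max_m + 1):
        eligible = [a for a in assessments if a.n_indications >= m]
        n_success = sum(a.success for a in eligible)
        recall = n_success / len(eligible) if eligible else None
        points[m] = RecallPoint(len(eligible), n_success, recall)
    return RecallCurve(points)


def _share_matrix(records: Sequence[DrugRecord]) -> np.ndarray:
    """Boolean D x D: do drugs i and j share at least one indication."""
    D = len(records)
    share = np.zeros((D, D), dtype=bool)
    sets = [r.indications for r in records]
    for i in range(D):
        for j in range(i + 1, D):
            if sets[i] & sets[j]:
                share[i, j] = share[j, i] = True
    return share


def random_null(
    records: Sequence[DrugRecord],
    max_m: int,
    n_trials: int = 10_000,
    seed: int = 0,
) -> NullEstimate:
    """Monte-Carlo null: each drug paired with a uniform random other drug.

    Every trial re-pairs all drugs and computes the recall curve exactly as
    :func:`recall_curve` does; the estimate is the mean over trials.
    """
    D = len(records)
    if D < 2:
        raise ValueError("need at least 2 drugs")
    share = _share_matrix(records)
    n_ind = np.array([len(r.indications) for r in records])
    rng = np.random.default_rng(seed)
    raw = rng.integers(0, D - 1, size=(n_trials, D))
    partners = raw + (raw >= np.arange(D)[None, :])  # skip self
    success = share[np.arange(D)[None, :], partners]  # trials x drugs
    mean: dict[int, float | None] = {}
    std: dict[int, float | None] = {}
    for m in range(1, max_m + 1):
        eligible = n_ind >= m
        if not eligible.any():
            mean[m] = None
            std[m] = None
            continue
        trial_recall = success[:, eligible].mean(axis=1)
        mean[m] = float(trial_recall.mean())
        std[m] = float(trial_recall.std(ddof=1))
    return NullEstimate(mean=mean, std=std, n_trials=n_trials, seed=seed)


def analytic_null(
    records: Sequence[DrugRecord], max_m: int
) -> dict[int, float | None]:
    """Exact expectation of :func:`random_null`.

    For each eligible drug the success probability under uniform partner
    choice is (number of other drugs sharing an indication) / (D - 1); the
    expected recall is the mean over eligible drugs.
    """
    D = len(records)
    if D < 2:
        raise ValueError("need at least 2 drugs")
    share = _share_matrix(records)
    p_success = share.sum(axis=1) / (D - 1)
    n_ind = np.array([len(r.indications) for r in records])
    out: dict[int, float | None] = {}
    for m in range(1, max_m + 1):
        eligible = n_ind >= m
        out[m] = float(p_success[eligible].mean()) if eligible.any() else None
    return out


def bw_replacements(
    assessments: Sequence[PairAssessment], records: Sequence[DrugRecord]
) -> BwReplacementReport:
    """Boxed-warning drugs whose neighbor lacks a BW and shares an indication."""
    by_id = {r.drug_id: r for r in records}
    replacements = []
    n_bw = 0
    for a in assessments:
        query = by_id[a.drug_id]
        neighbor = by_id[a.neighbor_id]
        if not query.has_boxed_warning:
            continue
        n_bw += 1
        if a.success and not neighbor.has_boxed_warning:
            replacements.append((a.drug_id, a.neighbor_id, a.shared_indications))
    return BwReplacementReport(
        replacements=replacements, n_bw_drugs=n_bw, n_replaceable=len(replacements)
    )


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value by the point-probability method.

    All 2x2 tables with the observed margins are enumerated under the
    hypergeometric distribution; the p-value sums the probabilities of every
    table no more likely than the observed one.  Computed in log space with
    ``lgamma``; no continuity correction.  A zero margin gives p = 1.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table must have a positive grand total")
    r1, r2, c1 = a + b, c + d, a + c
    if min(r1, r2, c1, b + d) == 0:
        return 1.0

    def logp(x: int) -> float:
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    logp_obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= logp_obs + 1e-7:  # relative tolerance for ties
            total += math.exp(lp)
    return min(1.0, total)


def atc_enrichment(
    assessments: Sequence[PairAssessment], records: Sequence[DrugRecord]
) -> list[AtcCategoryResult]:
    """Per ATC level-1 category: success proportion and Fisher's exact test.

    Drugs without an ATC code are excluded (and logged).  Each category is
    tested as in-category success/fail vs. out-of-category success/fail.
    Results are sorted by proportion descending, ties by category letter.
    """
    by_id = {r.drug_id: r for r in records}
    rows: list[tuple[str, bool]] = []
    for a in assessments:
        atc = by_id[a.drug_id].atc_level1
        if atc is None:
            logger.info("drug %s has no ATC code; excluded from enrichment", a.drug_id)
            continue
        rows.append((atc, a.success))
    if not rows:
        raise ValueError("no assessed drug has an ATC code")
    categories = sorted({atc for atc, _ in rows})
    n_success = sum(s for _, s in rows)
    n_total = len(rows)
    out: list[AtcCategoryResult] = []
    for cat in categories:
        s_in = sum(1 for atc, s in rows if atc == cat and s)
        f_in = sum(1 for atc, s in rows if atc == cat and not s)
        s_out = n_success - s_in
        f_out = (n_total - n_success) - f_in
        p = fisher_exact_two_sided([[s_in, f_in], [s_out, f_out]])
        out.append(
            AtcCategoryResult(
                category=cat,
                n_success_in=s_in,
                n_fail_in=f_in,
                n_success_out=s_out,
                n_fail_out=f_out,
                proportion=s_in / (s_in + f_in),
                p_value=p,
            )
        )
    out.sort(key=lambda r: (-r.proportion, r.category))
    return out
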