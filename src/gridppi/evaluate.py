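"""Ranking evaluation: hit-rate curves, success rates, and the HADDOCK
stage-specific reference scoring functions.

For one docking case, models are sorted by ascending score (lower = better)
and the hit rate at depth K is the fraction of the case's near-native models
found in the top K.  Across cases, the success rate at K is the fraction of
cases whose top K contains at least one near-native model; per-K medians and
quartiles of the hit-rate curves are reported up to N_min, the smallest
model count over cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankingResult",
    "EnergyTerms",
    "SuccessRateResult",
    "EvaluationError",
    "rank_models",
    "hit_rate_curve",
    "hit_rate_statistics",
    "success_rate",
    "haddock_score",
    "HADDOCK_WEIGHTS",
]


class EvaluationError(ValueError):
    pass


@dataclass
class RankingResult:
    case_id: str
    model_ids: list[str]       # best first
    scores: list[float]
    labels: list[int]          # 1 = near-native, aligned with model_ids
    hit_rate: np.ndarray       # hit_rate[K-1] for K = 1..n_models

    @property
    def n_hits(self) -> int:
        return int(sum(self.labels))

    @property
    def first_hit_rank(self) -> int | None:
        for rank, lab in enumerate(self.labels, start=1):
            if lab == 1:
                return rank
        return None


@dataclass
class EnergyTerms:
    e_vdw: float
    e_elec: float
    e_desol: float
    bsa: float


@dataclass
class SuccessRateResult:
    n_cases: int
    rates: dict[int, float]    # K -> fraction of successful cases


def rank_models(scores: dict[str, float]) -> list[str]:
    """Model ids ordered by ascending score; ties broken lexicographically."""
    for mid, s in scores.items():
        if not np.isfinite(s):
            raise EvaluationError(f"non-finite score for {mid!r}")
    return [mid for mid, _ in sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))]


def hit_rate_curve(scores: dict[str, float], labels: dict[str, int],
                   case_id: str = "") -> RankingResult:
    """Hit Rate(K) = n_hits(K) / M for K = 1..n_models.

    M is the case's total number of near-native models; a case with M = 0
    raises :class:`EvaluationError` (the curve is undefined).
    """
    ordering = rank_models(scores)
    ordered_labels = [int(labels[mid]) for mid in ordering]
    m = sum(ordered_labels)
    if m == 0:
        raise EvaluationError(f"case {case_id!r} has no near-native models")
    cum = np.cumsum(ordered_labels)
    return RankingResult(case_id=case_id, model_ids=ordering,
                         scores=[scores[mid] for mid in ordering],
                         labels=ordered_labels, hit_rate=cum / m)


def hit_rate_statistics(cases: list[RankingResult]) -> pd.DataFrame:
    """Per-K median and 25/75% quantiles of hit rates, for K <= N_min."""
    if not cases:
        raise EvaluationError("no cases to aggregate")
    n_min = min(len(c.model_ids) for c in cases)
    curves = np.stack([c.hit_rate[:n_min] for c in cases])
    return pd.DataFrame({
        "K": np.arange(1, n_min + 1),
        "median": np.median(curves, axis=0),
        "q25": np.percentile(curves, 25, axis=0),
        "q75": np.percentile(curves, 75, axis=0),
    })


def success_rate(cases: list[RankingResult],
                 ks: list[int] | None = None) -> SuccessRateResult:
    """Fraction of cases with >= 1 near-native model in the top K.

    Cases are counted over all supplied ranking results; a case whose first
    hit sits beyond K (or that has no hit at all) counts as a failure.
    """
    if not cases:
        raise EvaluationError("no cases")
    if ks is None:
        ks = list(range(1, min(len(c.model_ids) for c in cases) + 1))
    n = len(cases)
    rates = {}
    for k in ks:
        if k < 1:
            raise EvaluationError("K must be >= 1")
        successes = sum(1 for c in cases
                        if c.first_hit_rank is not None and c.first_hit_rank <= k)
        rates[int(k)] = successes / n
    return SuccessRateResult(n_cases=n, rates=rates)


#: Stage -> (w_vdw, w_elec, w_desol, w_bsa)
HADDOCK_WEIGHTS = {
    "it0": (0.01, 1.0, 1.0, -0.01),
    "it1": (1.0, 1.0, 1.0, -0.01),
    "itw": (1.0, 0.2, 1.0, 0.0),
}


def haddock_score(stage: str, terms: EnergyTerms) -> float:
    """Stage-specific weighted sum of vdW, electrostatic, desolvation, BSA.

    it0: 0.01 E_vdw + E_elec + E_desol - 0.01 BSA
    it1:      E_vdw + E_elec + E_desol - 0.01 BSA
    itw:      E_vdw + 0.2 E_elec + E_desol        (BSA ignored)
    """
    if stage not in HADDOCK_WEIGHTS:
        raise EvaluationError(f"unknown docking stage {stage!r}")
    wv, we, wd, wb = HADDOCK_WEIGHTS[stage]
    return (wv * terms.e_vdw + we * terms.e_elec + wd * terms.e_desol
            + wb * terms.bsa)


def ranking_report(cases: list[RankingResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model table and per-K summary (median/quartile hit rate + SR)."""
    rows = []
    for c in cases:
        for rank, (mid, score, lab) in enumerate(
                zip(c.model_ids, c.scores, c.labels), start=1):
            rows.append({"case_id": c.case_id, "rank": rank, "model_id": mid,
                         "score": score, "label": lab})
    per_model = pd.DataFrame(rows)
    summary = hit_rate_statistics(cases)
    sr = success_rate(cases, ks=list(summary["K"]))
    summary["success_rate"] = [sr.rates[int(k)] for k in summary["K"]]
    return per_model, summary
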