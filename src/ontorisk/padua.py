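"""The Padua linear VTE risk score.

Eleven boolean risk factors carry fixed integer weights (four 3-point, one
2-point, six 1-point); the sum is the Padua score and a score >= 4 marks a
patient as high risk.  Factors are consumed as structured flags scored by
clinicians, not extracted from text.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "PaduaFactors",
    "PaduaResult",
    "FACTOR_WEIGHTS",
    "HIGH_RISK_THRESHOLD",
    "padua_score",
    "cohort_padua_summary",
]

FACTOR_WEIGHTS: dict[str, int] = {
    "active_cancer_chemo": 3,
    "previous_vte": 3,
    "reduced_mobility": 3,
    "thrombophilic": 3,
    "recent_trauma_surgery": 2,
    "age_ge_70": 1,
    "heart_resp_failure": 1,
    "ami_ischemic_stroke": 1,
    "infection_rheumatologic": 1,
    "bmi_ge_30": 1,
    "glucocorticoid": 1,
}

HIGH_RISK_THRESHOLD = 4


@dataclass(frozen=True)
class PaduaFactors:
    active_cancer_chemo: bool = False
    previous_vte: bool = False
    reduced_mobility: bool = False
    thrombophilic: bool = False
    recent_trauma_surgery: bool = False
    age_ge_70: bool = False
    heart_resp_failure: bool = False
    ami_ischemic_stroke: bool = False
    infection_rheumatologic: bool = False
    bmi_ge_30: bool = False
    glucocorticoid: bool = False


@dataclass(frozen=True)
class PaduaResult:
    score: int
    high_risk: bool


def padua_score(f: PaduaFactors) -> PaduaResult:
    """Sum the weights of the set flags; high risk iff score >= 4."""
    score = sum(FACTOR_WEIGHTS[name] for name in FACTOR_WEIGHTS if getattr(f, name))
    return PaduaResult(score=score, high_risk=score >= HIGH_RISK_THRESHOLD)


def cohort_padua_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort factor prevalences, score moments and high-risk rates.

    ``flags`` has one row per patient with the 11 boolean factor columns and
    a ``cohort`` column.  Returns one row per (cohort, statistic): each
    factor's count and percentage, the mean and sd of the score, and the
    high-risk count and percentage.
    """
    required = set(FACTOR_WEIGHTS) | {"cohort"}
    missing = required - set(flags.columns)
    if missing:
        raise ValueError(f"flags table missing columns: {sorted(missing)}")
    rows = []
    for cohort, grp in flags.groupby("cohort"):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty cohort {cohort!r}")
        scores = grp.apply(
            lambda r: padua_score(PaduaFactors(**{k: bool(r[k]) for k in FACTOR_WEIGHTS})).score,
            axis=1,
        )
        high = int((scores >= HIGH_RISK_THRESHOLD).sum())
        rows.append(
            {
                "cohort": cohort,
                "statistic": "high_risk",
                "count": high,
                "percent": round(100.0 * high / n, 2),
            }
        )
        rows.append(
            {
                "cohort": cohort,
                "statistic": "score_mean_sd",
                "count": n,
                "percent": float("nan"),
                "mean": float(scores.mean()),
                "sd": float(scores.std(ddof=1)) if n > 1 else 0.0,
            }
        )
        for name in FACTOR_WEIGHTS:
            c = int(grp[name].astype(bool).sum())
            rows.append(
                {
                    "cohort": cohort,
                    "statistic": name,
                    "count": c,
                    "percent": round(100.0 * c / n, 2),
                }
            )
    return pd.DataFrame(rows)
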