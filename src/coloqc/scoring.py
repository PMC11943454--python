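"""Segment quality score and agreement statistics against expert BBPS.

The per-segment pixel statistics are converted to a 1-3 quality index
analogous to the Boston Bowel Preparation Scale (BBPS): a segment scores 3
when mucosal visualisation reaches 70% with residues at most 10%, scores 1
when mucosa is below 50% with residues above 15%, and 2 in between.  Unlike
the BBPS, which rates only residual content, the index reflects overall
examination quality because the underlying percentages also account for
artifacts and lumen.

Agreement with expert BBPS scores is quantified by the tie-corrected
Spearman rank correlation (scores and percentages are ordinal, heavily
tied series) and, for the categorical score-vs-score comparison, Cohen's
kappa.  The 21 per-segment records of the seven test colonoscopies (three
segments each: two expert raters' BBPS, the pixel-statistics score, and the
four class percentages) ship with the package as a CSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score


@dataclass
class ScoreThresholds:
    """Score-rule cutpoints (percentages).

    Score 3: mucosa >= ``mucosa_high`` and residue <= ``residue_low``.
    Score 1: mucosa <  ``mucosa_low``  and residue >  ``residue_high``.
    Otherwise score 2.
    """

    mucosa_high: float = 70.0
    residue_low: float = 10.0
    mucosa_low: float = 50.0
    residue_high: float = 15.0


@dataclass
class AgreementResult:
    spearman_rho: float
    kappa: float | None
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.spearman_rho <= 1.0 + 1e-12:
            raise ValueError("rho out of [-1, 1]")


def segment_score(
    mucosa_pct: float,
    residue_pct: float,
    thresholds: ScoreThresholds | None = None,
) -> int:
    """Quality score in {1, 2, 3} from segment mucosa/residue percentages."""
    t = thresholds or ScoreThresholds()
    for v in (mucosa_pct, residue_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    if mucosa_pct >= t.mucosa_high and residue_pct <= t.residue_low:
        return 3
    if mucosa_pct < t.mucosa_low and residue_pct > t.residue_high:
        return 1
    return 2


def spearman(x, y) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant series")
    return float(sps.spearmanr(x, y).statistic)


def cohens_kappa(x, y) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) over a shared category space."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("need two equal-length 1-D series")
    cats = np.unique(np.concatenate([x, y]))
    px = np.array([(x == c).mean() for c in cats])
    py = np.array([(y == c).mean() for c in cats])
    if float(px @ py) >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: chance agreement is 1")
    # integer category codes keep non-integer score scales (e.g. rater means)
    # acceptable to the backend
    return float(cohen_kappa_score(np.searchsorted(cats, x),
                                   np.searchsorted(cats, y)))


def load_table2() -> pd.DataFrame:
    """The packaged 21-record per-segment dataset of the seven test videos."""
    with resources.files("coloqc.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    assert len(df) == 21
    return df


def flag_inconsistent(
    df: pd.DataFrame, thresholds: ScoreThresholds | None = None
) -> pd.DataFrame:
    """Rows whose printed pixel score differs from the threshold rule.

    The published per-segment table contains rows that no reading of the
    stated cutpoints reproduces; they are surfaced here rather than fitted.
    """
    rule = df.apply(
        lambda r: segment_score(r.mucosa_pct, r.residue_pct, thresholds), axis=1
    )
    out = df.assign(rule_score=rule)
    return out[out.rule_score != out.pixel_score]


_RATERS = {"rater1": "bbps_rater1", "rater2": "bbps_rater2"}


def _bbps_series(df: pd.DataFrame, bbps_source: str) -> np.ndarray:
    if bbps_source == "mean":
        return ((df["bbps_rater1"] + df["bbps_rater2"]) / 2.0).to_numpy()
    try:
        return df[_RATERS[bbps_source]].to_numpy()
    except KeyError:
        raise ValueError(f"unknown BBPS source {bbps_source!r}") from None


def agreement_report(
    df: pd.DataFrame | None = None, bbps_source: str = "rater1"
) -> dict[str, AgreementResult]:
    """Agreement of expert BBPS with the pixel score and class percentages.

    Returns Spearman rho for BBPS vs pixel score, mucosa %, residue % and
    artifact %, plus Cohen's kappa for the score-vs-score comparison.
    """
    if df is None:
        df = load_table2()
    bbps = _bbps_series(df, bbps_source)
    out: dict[str, AgreementResult] = {}
    n = len(df)
    for name, col in (
        ("pixel_score", "pixel_score"),
        ("mucosa_pct", "mucosa_pct"),
        ("residue_pct", "residue_pct"),
        ("artifact_pct", "artifact_pct"),
    ):
        series = df[col].to_numpy()
        kappa = cohens_kappa(bbps, series) if name == "pixel_score" else None
        out[name] = AgreementResult(
            spearman_rho=spearman(bbps, series), kappa=kappa, n=n
        )
    return out
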