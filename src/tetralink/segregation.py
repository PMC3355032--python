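"""Chi-square segregation screening and two-tier distortion classification.

Each CP configuration has a Mendelian expectation (1:1 for markers
heterozygous in one parent, 1:2:1 codominant or 3:1 dominant for markers
heterozygous in both, equal classes for the fully informative SSR
configurations).  Markers are screened with a Pearson goodness-of-fit test
at a raw per-marker threshold (default p <= 0.005, no multiple-testing
correction, matching common practice for mapping populations; an optional
Bonferroni flag is exposed).

On top of the p-value screen sits a ratio rule for *highly* distorted
markers, which are excluded from framework-map construction: observed
majority:minority ratio above 2 when the expectation is 1:1, above 10 when
it is 3:1.  For 1:2:1 markers the 2:1 rule is applied to the two
homozygous classes (a natural extension; the source rules cover only the
1:1 and 3:1 cases).  ``highly_distorted`` implies membership in the
distorted set when counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

RATIOS = {
    ("lmxll", "codominant"): (1, 1),
    ("nnxnp", "codominant"): (1, 1),
    ("hkxhk", "codominant"): (1, 2, 1),
    ("hkxhk", "dominant"): (3, 1),
    ("efxeg", "codominant"): (1, 1, 1, 1),
    ("abxcd", "codominant"): (1, 1, 1, 1),
}


@dataclass
class SegregationResult:
    marker_id: str
    cp_code: str
    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    p: float
    distortion_class: str     # 'none' | 'distorted' | 'highly_distorted'


def expected_ratio(cp_code: str, scoring: str = "codominant") -> tuple[int, ...]:
    """Mendelian class ratio for a CP configuration."""
    try:
        return RATIOS[(cp_code, scoring)]
    except KeyError:
        raise InvalidParameterError(
            f"no expected ratio for code {cp_code!r} with scoring {scoring!r}")


def chi_square_gof(observed, ratio) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of observed class counts against a ratio."""
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.shape != rat.shape:
        raise InvalidParameterError(
            f"dimension mismatch: {obs.shape} counts vs {rat.shape} ratio")
    if obs.sum() <= 0:
        raise InvalidParameterError("no genotyped individuals")
    if np.any(rat <= 0):
        raise InvalidParameterError("expected ratio entries must be positive")
    expected = obs.sum() * rat / rat.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def classify_distortion(observed, cp_code: str, alpha: float = 0.005,
                        scoring: str = "codominant") -> str:
    """Two-tier distortion class for one marker's class counts."""
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    obs = np.asarray(observed, dtype=float)
    if obs.sum() <= 0:
        raise InvalidParameterError("no genotyped individuals")
    ratio = expected_ratio(cp_code, scoring)
    if ratio == (1, 1):
        lo, hi = sorted(obs)
        if lo == 0 or hi / lo > 2:
            return "highly_distorted"
    elif ratio == (3, 1):
        lo, hi = sorted(obs)
        if lo == 0 or hi / lo > 10:
            return "highly_distorted"
    elif ratio == (1, 2, 1):
        lo, hi = sorted((obs[0], obs[2]))
        if lo == 0 or hi / lo > 2:
            return "highly_distorted"
    _, _, p = chi_square_gof(obs, ratio)
    return "distorted" if p <= alpha else "none"


def test_marker(marker_id: str, cp_code: str, observed,
                alpha: float = 0.005, scoring: str = "codominant"
                ) -> SegregationResult:
    ratio = expected_ratio(cp_code, scoring)
    chi2, df, p = chi_square_gof(observed, ratio)
    cls = classify_distortion(observed, cp_code, alpha, scoring)
    return SegregationResult(marker_id, cp_code, tuple(int(o) for o in observed),
                             ratio, chi2, df, p, cls)


def screen_markers(cp_calls: dict, alpha: float = 0.005,
                   bonferroni: bool = False) -> pd.DataFrame:
    """Segregation screen over a set of CP calls.

    ``cp_calls`` maps marker_id -> CPCall.  Counts are taken over
    non-missing tokens in the canonical token order of each code.  With
    ``bonferroni`` the threshold becomes alpha / n_markers.
    """
    from .calling import CP_TOKENS, MISSING

    eff_alpha = alpha / max(len(cp_calls), 1) if bonferroni else alpha
    rows = []
    for marker_id, call in sorted(cp_calls.items()):
        tokens = CP_TOKENS[call.cp_code]
        counts = [sum(1 for t in call.calls.values() if t == tok)
                  for tok in tokens]
        if sum(counts) == 0:
            continue
        res = test_marker(marker_id, call.cp_code, counts, eff_alpha)
        rows.append({
            "marker_id": marker_id, "cp_code": call.cp_code,
            "observed": ":".join(str(c) for c in res.observed),
            "chi2": res.chi2, "df": res.df, "p": res.p,
            "distortion_class": res.distortion_class})
    return pd.DataFrame(rows, columns=["marker_id", "cp_code", "observed",
                                       "chi2", "df", "p", "distortion_class"])
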