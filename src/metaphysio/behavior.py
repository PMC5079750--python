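"""Behavioural analysis: exclusions, binning, type-1 SDT, and 2x2 tests.

Trial-level exclusions remove the staircase burn-in, missed responses, and
RT outliers before any modelling.  Type-1 signal detection treats "right"
as the signal response: hit = P(respond right | rightward stimulus),
false alarm = P(respond right | leftward stimulus), d' = z(hit) - z(fa),
c = -(z(hit) + z(fa))/2.  Confidence ratings are reduced to per-subject
empirical quartile bins for the meta-d' model.  Condition effects are
tested with classical 2x2 repeated-measures ANOVAs computed from 1-df
difference-score contrasts (each effect's F equals the squared paired t).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "bin_confidence_quartiles",
    "Type1SDT",
    "compute_type1_sdt",
    "compute_masking_dprime_ci",
    "rm_anova_2x2",
    "condition_parameter_table",
]


@dataclass
class ExclusionReport:
    """Per-rule exclusion bookkeeping; kept + excluded = input."""

    n_input: int
    n_burn_in: int
    n_missed: int
    n_rt_outlier: int
    n_kept: int

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def apply_exclusions(
    trials: pd.DataFrame,
    burn_in_fraction: float | None = 0.25,
    burn_in_blocks: int | None = None,
    rt_z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove burn-in, missed, and RT-outlier trials.

    The first ``burn_in_fraction`` of trials (default 25%, the staircase
    stabilization period) are dropped first; alternatively pass
    ``burn_in_blocks`` to drop whole initial blocks.  Missed trials are then
    removed, and finally trials with |z-scored RT| above ``rt_z_threshold``
    (z computed on the surviving trials; a zero-variance RT distribution
    yields z = 0 by convention, excluding nothing).
    """
    n_input = len(trials)
    if n_input == 0:
        return trials.copy(), ExclusionReport(0, 0, 0, 0, 0)
    if burn_in_blocks is not None:
        keep = trials["block"] >= burn_in_blocks
    else:
        n_burn = int(round((burn_in_fraction or 0.0) * n_input))
        keep = pd.Series(np.arange(n_input) >= n_burn, index=trials.index)
    n_burn_in = int((~keep).sum())
    kept = trials[keep]

    missed = kept["missed"].astype(bool)
    n_missed = int(missed.sum())
    kept = kept[~missed]

    rt = kept["rt"].to_numpy(dtype=float)
    sd = rt.std()
    z = (rt - rt.mean()) / sd if sd > 0 else np.zeros_like(rt)
    outlier = np.abs(z) > rt_z_threshold
    n_rt = int(outlier.sum())
    kept = kept[~outlier]

    report = ExclusionReport(
        n_input=n_input,
        n_burn_in=n_burn_in,
        n_missed=n_missed,
        n_rt_outlier=n_rt,
        n_kept=len(kept),
    )
    return kept.copy(), report


def bin_confidence_quartiles(confidence: np.ndarray) -> np.ndarray:
    """Per-subject empirical quartile bins (1..4) of 0-100 confidence.

    Bin edges are the 25/50/75% empirical quantiles taken as order
    statistics (so edges are actual data values and the binning is purely
    rank-based, hence exactly invariant to strictly monotone transforms of
    the scale); values exactly at an edge fall in the lower bin, so tied
    values always share a bin.  With
    fewer than 4 distinct values the empirical quartiles collapse, and the
    function falls back to fixed equal-width bins [0,25), [25,50), [50,75),
    [75,100] (warning logged).
    """
    confidence = np.asarray(confidence, dtype=float)
    if np.any((confidence < 0) | (confidence > 100)):
        raise ValueError("confidence values must lie in [0, 100]")
    if len(np.unique(confidence)) < 4:
        logger.warning("fewer than 4 distinct confidence values: equal-width fallback")
        warnings.warn("fewer than 4 distinct confidence values: equal-width bins", stacklevel=2)
        edges = np.array([25.0, 50.0, 75.0])
        return 1 + np.sum(confidence[:, None] >= edges[None, :], axis=1)
    edges = np.quantile(confidence, [0.25, 0.5, 0.75], method="lower")
    return 1 + np.sum(confidence[:, None] > edges[None, :], axis=1)


@dataclass
class Type1SDT:
    """Type-1 sensitivity and bias for one condition."""

    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    n_trials: int


def _rates_with_correction(
    n_hit: int, n_signal: int, n_fa: int, n_noise: int
) -> tuple[float, float]:
    """Hit/FA rates with the log-linear correction when any rate is 0 or 1."""
    hit, fa = n_hit / n_signal, n_fa / n_noise
    if hit in (0.0, 1.0) or fa in (0.0, 1.0):
        hit = (n_hit + 0.5) / (n_signal + 1)
        fa = (n_fa + 0.5) / (n_noise + 1)
    return hit, fa


def compute_type1_sdt(trials: pd.DataFrame) -> Type1SDT:
    """d' and criterion for one condition's trials.

    "Right" is the signal response: hit = P(right | rightward stimulus),
    fa = P(right | leftward stimulus).  The log-linear correction is
    applied when any rate is degenerate.
    """
    right = trials["side"] == "right"
    left = trials["side"] == "left"
    if not right.any() or not left.any():
        raise ValueError("both stimulus sides must be present")
    resp_right = trials["choice"] == "right"
    hit, fa = _rates_with_correction(
        int((right & resp_right).sum()), int(right.sum()),
        int((left & resp_right).sum()), int(left.sum()),
    )
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return Type1SDT(
        d_prime=float(zh - zf),
        criterion_c=float(-0.5 * (zh + zf)),
        hit_rate=float(hit),
        fa_rate=float(fa),
        n_trials=len(trials),
    )


def compute_masking_dprime_ci(
    subject_trials: dict | pd.DataFrame, confidence_level: float = 0.95
) -> dict:
    """Masking efficacy: across-subject d' for cue-valence detection.

    Accepts either a DataFrame with a ``subject`` column or a mapping
    subject -> trials; trials need ``cue`` (true valence: disgust/neutral)
    and ``response`` (reported valence) columns.  Computes a per-subject d'
    (hit = P(report disgust | disgust)), then the across-subject mean and
    t-based CI.  The cue counts as successfully masked when the CI spans
    zero.
    """
    if isinstance(subject_trials, pd.DataFrame):
        groups = {k: g for k, g in subject_trials.groupby("subject")}
    else:
        groups = dict(subject_trials)
    dprimes = []
    for _, g in sorted(groups.items()):
        signal = g["cue"] == "disgust"
        noise = g["cue"] == "neutral"
        said = g["response"] == "disgust"
        hit, fa = _rates_with_correction(
            int((signal & said).sum()), int(signal.sum()),
            int((noise & said).sum()), int(noise.sum()),
        )
        dprimes.append(float(stats.norm.ppf(hit) - stats.norm.ppf(fa)))
    dprimes = np.asarray(dprimes)
    mean = float(dprimes.mean())
    if len(dprimes) < 2:
        warnings.warn("single subject: point estimate only, no CI", stacklevel=2)
        return {"d_prime_mean": mean, "ci": None, "masked": None, "per_subject": dprimes}
    sem = dprimes.std(ddof=1) / np.sqrt(len(dprimes))
    tcrit = stats.t.ppf(0.5 + confidence_level / 2, df=len(dprimes) - 1)
    ci = (mean - tcrit * sem, mean + tcrit * sem)
    return {
        "d_prime_mean": mean,
        "ci": ci,
        "masked": bool(ci[0] <= 0.0 <= ci[1]),
        "per_subject": dprimes,
    }


def rm_anova_2x2(cells: pd.DataFrame) -> dict:
    """2x2 repeated-measures ANOVA (cue valence x variance) plus follow-ups.

    ``cells`` has one row per subject and columns NL, NH, DL, DH (neutral /
    disgust x low / high variance).  With 1 df per effect, each F is the
    squared paired t of the corresponding difference contrast and
    sphericity is moot.  Partial eta^2 = t^2 / (t^2 + df_error).

    Returns effect -> {F, p, df, partial_eta_sq} for ``cue``, ``variance``
    and ``interaction``, plus simple-effect paired t-tests ``NH_vs_NL`` and
    ``DH_vs_DL``.
    """
    required = {"NL", "NH", "DL", "DH"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cells must contain columns {sorted(required)}")
    if cells[sorted(required)].isna().any().any():
        raise ValueError("missing cells")
    if len(cells) < 3:
        raise ValueError("need >= 3 subjects")
    nl, nh = cells["NL"].to_numpy(float), cells["NH"].to_numpy(float)
    dl, dh = cells["DL"].to_numpy(float), cells["DH"].to_numpy(float)
    n = len(cells)

    def contrast_test(scores: np.ndarray) -> dict:
        sd = scores.std(ddof=1)
        if sd == 0:
            t = 0.0
        else:
            t = float(scores.mean() / (sd / np.sqrt(n)))
        F = t**2
        p = float(stats.f.sf(F, 1, n - 1)) if sd > 0 else 1.0
        return {
            "F": F,
            "p": p,
            "df": (1, n - 1),
            "partial_eta_sq": F / (F + (n - 1)) if (F + n - 1) > 0 else 0.0,
        }

    results = {
        "cue": contrast_test((dl + dh) / 2 - (nl + nh) / 2),
        "variance": contrast_test((nh + dh) / 2 - (nl + dl) / 2),
        "interaction": contrast_test((dh - dl) - (nh - nl)),
    }

    def paired_t(a: np.ndarray, b: np.ndarray) -> dict:
        d = a - b
        if d.std(ddof=1) == 0:
            return {"t": 0.0, "p": 1.0, "mean_diff": float(d.mean())}
        t, p = stats.ttest_rel(a, b)
        return {"t": float(t), "p": float(p), "mean_diff": float(d.mean())}

    results["NH_vs_NL"] = paired_t(nh, nl)
    results["DH_vs_DL"] = paired_t(dh, dl)
    return results


def condition_parameter_table(
    trials_by_subject: dict[int, pd.DataFrame],
    fit_metad: bool = True,
    m_bias_definition: str = "criterion_spread",
) -> pd.DataFrame:
    """Per-subject per-condition SDT and meta-d' parameter table.

    Applies per-subject quartile binning across *all* analysed trials (so
    condition-wise confidence biases survive the binning), then computes
    type-1 SDT and, optionally, the meta-d' fit within each cue x variance
    cell.  Columns: subject, cue, variance, d_prime, c, meta_d, m_ratio,
    m_bias, n_trials.
    """
    from .metad import confidence_counts, fit_meta_d

    rows = []
    for subject, trials in sorted(trials_by_subject.items()):
        trials = trials.copy()
        trials["conf_bin"] = bin_confidence_quartiles(trials["confidence"].to_numpy())
        for cue in ("neutral", "disgust"):
            for variance in ("low", "high"):
                cell = trials[(trials["cue"] == cue) & (trials["variance"] == variance)]
                if len(cell) == 0:
                    continue
                sdt = compute_type1_sdt(cell)
                row = dict(
                    subject=subject,
                    cue=cue,
                    variance=variance,
                    d_prime=sdt.d_prime,
                    c=sdt.criterion_c,
                    meta_d=np.nan,
                    m_ratio=np.nan,
                    m_bias=np.nan,
                    n_trials=len(cell),
                )
                if fit_metad and sdt.d_prime > 0:
                    counts = confidence_counts(
                        cell["side"].to_numpy(),
                        cell["choice"].to_numpy(),
                        cell["conf_bin"].to_numpy(),
                    )
                    fit = fit_meta_d(counts, m_bias_definition=m_bias_definition)
                    row.update(meta_d=fit.meta_d, m_ratio=fit.m_ratio, m_bias=fit.m_bias)
                rows.append(row)
    return pd.DataFrame(rows)
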