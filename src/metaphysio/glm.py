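"""Trial-wise GLM on epoched physiology and cluster-based permutation tests.

At every sampled time point of the epoch, an ordinary-least-squares model
relates the trial-by-trial signal amplitude to ten regressors: intercept,
sensory noise (variance condition), cue valence, confidence, the
noise x confidence, cue x confidence, cue x noise and
cue x noise x confidence interactions, and two nuisance covariates (signal
mean and RT).  Group inference uses the summary-statistic approach: a
one-sample t across subjects on each regressor's beta time course,
thresholded at |t| > 2, with contiguous supra-threshold clusters assessed
against a sign-flip permutation null of the maximum cluster extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "REGRESSORS",
    "DesignInfo",
    "build_design_matrix",
    "TrialwiseGLM",
    "Cluster",
    "ClusterResult",
    "ClusterPermutationTest",
    "group_cluster_permutation",
    "extract_condition_means",
]

#: fixed column order of the design matrix
REGRESSORS = (
    "intercept",
    "noise",
    "cue",
    "confidence",
    "noise_x_confidence",
    "cue_x_confidence",
    "cue_x_noise",
    "cue_x_noise_x_confidence",
    "mean_orientation",
    "rt",
)


@dataclass
class DesignInfo:
    """Design matrix plus per-column normalization metadata."""

    X: pd.DataFrame
    center: dict[str, float]
    scale: dict[str, float]

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy()


def build_design_matrix(
    trials: pd.DataFrame, include_cue_by_noise: bool = True
) -> DesignInfo:
    """Build the z-scored trial-wise design matrix.

    Coding: noise low = -1 / high = +1; cue neutral = -1 / disgust = +1;
    confidence, mean orientation and RT enter as raw continuous values.
    Interactions are products of the coded main-effect columns.  Every
    non-intercept column is then z-scored across trials (population SD), so
    betas are in signal units per 1 SD of regressor.

    Raises
    ------
    ValueError
        If any column is constant or the matrix is rank deficient, naming
        the offending column.
    """
    noise = np.where(trials["variance"].to_numpy() == "high", 1.0, -1.0)
    cue = np.where(trials["cue"].to_numpy() == "disgust", 1.0, -1.0)
    conf = trials["confidence"].to_numpy(dtype=float)
    raw = {
        "noise": noise,
        "cue": cue,
        "confidence": conf,
        "noise_x_confidence": noise * conf,
        "cue_x_confidence": cue * conf,
        "cue_x_noise": cue * noise,
        "cue_x_noise_x_confidence": cue * noise * conf,
        "mean_orientation": trials["signal_mean"].to_numpy(dtype=float),
        "rt": trials["rt"].to_numpy(dtype=float),
    }
    if not include_cue_by_noise:
        raw.pop("cue_x_noise")
    cols = {"intercept": np.ones(len(trials))}
    center: dict[str, float] = {"intercept": 0.0}
    scale: dict[str, float] = {"intercept": 1.0}
    for name, x in raw.items():
        mu, sd = float(np.mean(x)), float(np.std(x))
        if sd == 0.0:
            raise ValueError(f"design column {name!r} is constant (zero variance)")
        cols[name] = (x - mu) / sd
        center[name], scale[name] = mu, sd
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        names = X.columns[1:]
        raise ValueError(
            f"design matrix is rank deficient (columns {names[i]!r} and "
            f"{names[j]!r} are collinear)"
        )
    return DesignInfo(X=X, center=center, scale=scale)


class TrialwiseGLM(BaseEstimator, RegressorMixin):
    """OLS fit independently at each time point of an epoch matrix.

    ``fit(X, Y)`` takes the design (n_trials x n_regressors; DataFrame or
    array) and the signal (n_trials x n_times); ``coef_`` is
    (n_regressors x n_times).
    """

    def fit(self, X, Y):  # noqa: N803
        if isinstance(X, DesignInfo):
            X = X.X
        self.feature_names_in_ = (
            np.asarray(X.columns) if hasattr(X, "columns") else None
        )
        Xv = np.asarray(X, dtype=float)
        Yv = np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        if Xv.shape[0] != Yv.shape[0]:
            raise ValueError("X and Y must have the same number of trials")
        if Xv.shape[1] > Xv.shape[0]:
            raise ValueError("more regressors than trials")
        coef, _, rank, _ = np.linalg.lstsq(Xv, Yv, rcond=None)
        self.coef_ = coef
        self.rank_ = int(rank)
        self.n_features_in_ = Xv.shape[1]
        return self

    def predict(self, X):  # noqa: N803
        if isinstance(X, DesignInfo):
            X = X.X
        return np.asarray(X, dtype=float) @ self.coef_


@dataclass
class Cluster:
    """One supra-threshold cluster of the group t time course."""

    sign: str  # "positive" or "negative"
    start_idx: int
    end_idx: int  # inclusive
    start_ms: float
    end_ms: float
    extent: int
    mass: float
    p_perm: float
    peak_beta: float
    peak_ms: float


@dataclass
class ClusterResult:
    """Cluster-permutation outcome for one regressor."""

    regressor: str
    t_obs: np.ndarray
    times_ms: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm <= alpha]


def _clusters_from_t(t: np.ndarray, height: float, sign: int) -> list[tuple[int, int]]:
    """Maximal runs where sign*t > height; returns (start, end_inclusive)."""
    mask = (sign * t) > height
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts, ends))


def _cluster_stat(t: np.ndarray, runs, statistic: str) -> np.ndarray:
    if statistic == "extent":
        return np.array([e - s + 1 for s, e in runs], dtype=float)
    if statistic == "mass":
        return np.array([np.abs(t[s : e + 1]).sum() for s, e in runs], dtype=float)
    raise ValueError(f"unknown cluster statistic {statistic!r}")


def _one_sample_t(mean: np.ndarray, sq_mean: np.ndarray, n: int) -> np.ndarray:
    var = (sq_mean - mean**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


class ClusterPermutationTest(BaseEstimator):
    """Sign-flip max-cluster permutation test on one regressor's betas.

    Parameters
    ----------
    t_height : float
        Height threshold on the group t statistic (applied at +t_height for
        the positive test and -t_height for the negative test; the two
        one-sided tests are run separately, each at ``cluster_alpha``).
    n_perm : int
        Number of random whole-subject sign flips (default 500).
    cluster_alpha : float
        Nominal cluster-level alpha for `significant` bookkeeping.
    statistic : {"extent", "mass"}
        Cluster-level statistic compared against the permutation null of
        its maximum.
    random_state : int or None
        Seed for the sign-flip draws (recorded for provenance).

    Fitted attributes: ``t_obs_``, ``result_`` (a :class:`ClusterResult`),
    ``null_max_pos_``, ``null_max_neg_``.
    """

    def __init__(
        self,
        t_height: float = 2.0,
        n_perm: int = 500,
        cluster_alpha: float = 0.05,
        statistic: str = "extent",
        random_state: int | None = None,
    ):
        self.t_height = t_height
        self.n_perm = n_perm
        self.cluster_alpha = cluster_alpha
        self.statistic = statistic
        self.random_state = random_state

    def fit(self, X, times_ms: np.ndarray | None = None, regressor: str = ""):  # noqa: N803
        """X: (n_subjects, n_times) beta time courses for one regressor."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_subjects, n_times)")
        n_sub, n_t = X.shape
        if n_sub < 5:
            raise ValueError("need >= 5 subjects for group inference")
        if self.n_perm < 100:
            import warnings

            warnings.warn("n_perm < 100 gives a coarse permutation null", stacklevel=2)
        if times_ms is None:
            times_ms = np.arange(n_t, dtype=float)
        times_ms = np.asarray(times_ms, dtype=float)

        sq_mean = np.mean(X**2, axis=0)
        t_obs = _one_sample_t(X.mean(axis=0), sq_mean, n_sub)

        rng = np.random.default_rng(self.random_state)
        flips = rng.choice([-1.0, 1.0], size=(self.n_perm, n_sub))
        perm_means = flips @ X / n_sub  # (n_perm, n_times)
        null_max_pos = np.zeros(self.n_perm)
        null_max_neg = np.zeros(self.n_perm)
        for k in range(self.n_perm):
            t_k = _one_sample_t(perm_means[k], sq_mean, n_sub)
            for sign, store in ((1, null_max_pos), (-1, null_max_neg)):
                runs = _clusters_from_t(t_k, self.t_height, sign)
                if runs:
                    store[k] = _cluster_stat(t_k, runs, self.statistic).max()

        mean_beta = X.mean(axis=0)
        clusters: list[Cluster] = []
        for sign, label, null in (
            (1, "positive", null_max_pos),
            (-1, "negative", null_max_neg),
        ):
            runs = _clusters_from_t(t_obs, self.t_height, sign)
            stats_ = _cluster_stat(t_obs, runs, self.statistic)
            for (s, e), st in zip(runs, stats_):
                p = float((1 + np.sum(null >= st)) / (self.n_perm + 1))
                seg = mean_beta[s : e + 1]
                pk = int(np.argmax(sign * seg))
                clusters.append(
                    Cluster(
                        sign=label,
                        start_idx=int(s),
                        end_idx=int(e),
                        start_ms=float(times_ms[s]),
                        end_ms=float(times_ms[e]),
                        extent=int(e - s + 1),
                        mass=float(np.abs(t_obs[s : e + 1]).sum()),
                        p_perm=p,
                        peak_beta=float(seg[pk]),
                        peak_ms=float(times_ms[s + pk]),
                    )
                )
        self.t_obs_ = t_obs
        self.null_max_pos_ = null_max_pos
        self.null_max_neg_ = null_max_neg
        self.result_ = ClusterResult(
            regressor=regressor, t_obs=t_obs, times_ms=times_ms, clusters=clusters
        )
        return self


def group_cluster_permutation(
    betas: np.ndarray,
    regressor: str | int,
    regressor_names=REGRESSORS,
    times_ms: np.ndarray | None = None,
    t_height: float = 2.0,
    n_perm: int = 500,
    cluster_alpha: float = 0.05,
    statistic: str = "extent",
    random_state: int | None = None,
) -> ClusterResult:
    """Run the cluster permutation test for one regressor.

    ``betas`` is either (n_subjects, n_times) for the chosen regressor or
    the full (n_subjects, n_regressors, n_times) stack from which the
    regressor is selected by name or index.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 3:
        idx = (
            list(regressor_names).index(regressor)
            if isinstance(regressor, str)
            else int(regressor)
        )
        betas = betas[:, idx, :]
        name = regressor if isinstance(regressor, str) else str(regressor_names[idx])
    else:
        name = str(regressor)
    test = ClusterPermutationTest(
        t_height=t_height,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
        statistic=statistic,
        random_state=random_state,
    )
    test.fit(betas, times_ms=times_ms, regressor=name)
    return test.result_


def extract_condition_means(
    epochs_data: np.ndarray,
    trials: pd.DataFrame,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    design: DesignInfo | None = None,
    nuisance: tuple[str, ...] = ("mean_orientation", "rt"),
    median_split_confidence: bool = False,
) -> pd.DataFrame:
    """Adjusted per-condition mean response within a significant window.

    The full GLM is fit to the epochs and the contribution of the nuisance
    regressors is subtracted before averaging, so condition means are
    controlled for trial difficulty (signal mean) and RT.  With
    ``median_split_confidence`` the cells are cue x (high/low confidence,
    split at each cue condition's median) instead of cue x variance.
    """
    design = design or build_design_matrix(trials)
    X = design.values
    glm = TrialwiseGLM().fit(X, epochs_data)
    cols = design.columns
    nuis_idx = [cols.index(n) for n in nuisance if n in cols]
    adjusted = epochs_data - X[:, nuis_idx] @ glm.coef_[nuis_idx]

    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window contains no samples")
    per_trial = adjusted[:, sel].mean(axis=1)

    trials = trials.reset_index(drop=True)
    if median_split_confidence:
        labels = []
        for _, row in trials.iterrows():
            med = trials.loc[trials["cue"] == row["cue"], "confidence"].median()
            lvl = "high_conf" if row["confidence"] > med else "low_conf"
            labels.append(f"{row['cue']}_{lvl}")
        group = pd.Series(labels, name="condition")
    else:
        group = (trials["cue"] + "_" + trials["variance"]).rename("condition")
    out = (
        pd.DataFrame({"condition": group, "value": per_trial})
        .groupby("condition", as_index=False)["value"]
        .agg(["mean", "count"])
        .reset_index()
    )
    if (out["count"] == 0).any():
        raise ValueError("empty condition cell")
    return out
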