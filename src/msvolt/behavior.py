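"""Linking volatility to behavior: subsequent-memory classification and
directional region-level connectivity contrasts.

Classification: an L2-penalized logistic regression predicts later recall
from encoding-period features (per-electrode epoch-mean volatility, or
electrode × frequency z-scored log power), evaluated by leave-one-session-out
nested cross-validation with the penalty chosen by an inner CV, scored by ROC
AUC.

Connectivity: the fitted persistence matrix β is aggregated into a
region × region directed network C_{I→J} (mean lag-one influence of region I
electrodes on region J electrodes); the recalled-vs-non-recalled contrast
Δ_{I→J} = C^R − C^{NR} is tested across subjects with one-sample t-tests and
Benjamini–Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneGroupOut

__all__ = [
    "FeatureMatrix",
    "ConnectivityContrast",
    "build_features",
    "roc_auc",
    "nested_cv_classify",
    "region_connectivity",
    "sme_contrast",
    "group_test_fdr",
    "fit_condition_contrast",
    "DEFAULT_PENALTY_GRID",
]

#: inverse-regularization grid for the L2 logistic classifier
DEFAULT_PENALTY_GRID = np.logspace(-4, 4, 9)


@dataclass
class FeatureMatrix:
    """Events × features design with recall labels and session ids."""

    X: np.ndarray
    y: np.ndarray
    session_ids: np.ndarray
    subject_id: str = ""
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y).astype(int)
        self.session_ids = np.asarray(self.session_ids)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be events × features aligned with y")
        if np.isnan(self.X).any():
            ev, ft = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(f"NaN feature: event {ev}, feature {ft}")
        if np.unique(self.y).size < 2:
            raise ValueError("need both classes present overall")


@dataclass
class ConnectivityContrast:
    """Group-level Δ network with per-cell statistics (regions × regions)."""

    regions: list[str]
    delta: pd.DataFrame
    per_subject: np.ndarray        # (subjects, regions, regions), NaN = missing
    t: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_subjects: pd.DataFrame

    def __post_init__(self) -> None:
        off = ~np.eye(len(self.regions), dtype=bool)
        both = off & self.p.notna().to_numpy() & self.p_adj.notna().to_numpy()
        if not np.all(self.p_adj.to_numpy()[both]
                      >= self.p.to_numpy()[both] - 1e-12):
            raise ValueError("adjusted p must be >= raw p")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: region_from, region_to, delta_mean, t, p, p_adj, n."""
        rows = []
        for i in self.regions:
            for j in self.regions:
                if i == j:
                    continue
                rows.append({"region_from": i, "region_to": j,
                             "delta_mean": self.delta.loc[i, j],
                             "t": self.t.loc[i, j], "p": self.p.loc[i, j],
                             "p_adj": self.p_adj.loc[i, j],
                             "n_subjects": self.n_subjects.loc[i, j]})
        return pd.DataFrame(rows)


def _zscore_within_session(X: np.ndarray, session_ids: np.ndarray) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    for sess in np.unique(session_ids):
        sel = session_ids == sess
        block = X[sel]
        sd = block.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        out[sel] = (block - block.mean(axis=0)) / sd
    return out


def build_features(vol_or_power, labels: pd.DataFrame, mode: str,
                   subject_id: str = "") -> FeatureMatrix:
    """Assemble the classifier design matrix.

    mode="volatility": ``vol_or_power`` is the (events, channels, samples)
    posterior-mean log-volatility; features are the per-electrode epoch means,
    z-scored within session (J features).  mode="power": ``vol_or_power`` is
    a PowerTensor (already log, epoch-averaged); features are the flattened
    electrode × frequency powers, z-scored within session.
    """
    y = labels["recalled"].to_numpy().astype(int)
    sessions = labels["session"].to_numpy()
    if len(y) < 2:
        raise ValueError("need at least 2 events")
    if mode == "volatility":
        x = np.asarray(vol_or_power, dtype=float)
        X = x.mean(axis=-1)
        names = [f"vol_ch{j}" for j in range(X.shape[1])]
    elif mode == "power":
        pt = vol_or_power
        E, J, F = pt.power.shape
        X = pt.power.reshape(E, J * F)
        names = [f"pow_ch{j}_f{f:g}" for j in range(J) for f in pt.freqs]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    X = _zscore_within_session(X, sessions)
    return FeatureMatrix(X=X, y=y, session_ids=sessions,
                         subject_id=subject_id, feature_names=names)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (ties counted ½); errors on one-class input."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def _fit_lr(X, y, C):
    # L2 penalty (the sklearn default) with inverse strength C
    return LogisticRegression(C=C, solver="lbfgs", max_iter=2000).fit(X, y)


def nested_cv_classify(fm: FeatureMatrix,
                       penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID
                       ) -> pd.DataFrame:
    """Leave-one-session-out nested cross-validation.

    For each held-out session, an inner leave-one-session-out CV over the
    remaining sessions picks the penalty with the best mean AUC; the model is
    refit on all N−1 sessions with that penalty and scored on the held-out
    session.  Requires ≥3 sessions (so the inner CV is itself cross-session).
    Held-out sessions with a single class are skipped with a warning.
    Deterministic given the data and grid.
    """
    sessions = np.unique(fm.session_ids)
    if sessions.size < 3:
        raise ValueError("nested session-wise CV needs at least 3 sessions")
    logo = LeaveOneGroupOut()
    rows = []
    for train, test in logo.split(fm.X, fm.y, groups=fm.session_ids):
        held = fm.session_ids[test][0]
        if np.unique(fm.y[test]).size < 2:
            warnings.warn(f"session {held!r} has one class; fold skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        Xtr, ytr, gtr = fm.X[train], fm.y[train], fm.session_ids[train]
        inner_scores = []
        for C in penalty_grid:
            aucs = []
            for itr, ite in logo.split(Xtr, ytr, groups=gtr):
                if (np.unique(ytr[ite]).size < 2
                        or np.unique(ytr[itr]).size < 2):
                    continue
                model = _fit_lr(Xtr[itr], ytr[itr], C)
                aucs.append(roc_auc(model.decision_function(Xtr[ite]),
                                    ytr[ite]))
            inner_scores.append(np.mean(aucs) if aucs else -np.inf)
        best_C = penalty_grid[int(np.argmax(inner_scores))]
        model = _fit_lr(Xtr, ytr, best_C)
        auc = roc_auc(model.decision_function(fm.X[test]), fm.y[test])
        rows.append({"session": held, "auc": auc, "C": best_C,
                     "n_test": test.size})
    return pd.DataFrame(rows)


def region_connectivity(beta: np.ndarray, region_labels: list[str]
                        ) -> pd.DataFrame:
    """Aggregate β into the directed region network C (index=I/source,
    columns=J/target).

    C_{I→J} averages β[j, i] over target electrodes j ∈ J (rows) and source
    electrodes i ∈ I (columns): the mean lag-one influence of region I on
    region J.  Pairs with no electrodes on either side are NaN.
    """
    beta = np.asarray(beta, dtype=float)
    if len(region_labels) != beta.shape[0]:
        raise ValueError("every electrode needs a region label")
    regions = sorted(set(region_labels))
    C = pd.DataFrame(np.nan, index=regions, columns=regions)
    labels = np.asarray(region_labels)
    for I in regions:
        cols = labels == I
        for J in regions:
            rows = labels == J
            if cols.any() and rows.any():
                C.loc[I, J] = beta[np.ix_(rows, cols)].mean()
    return C


def sme_contrast(C_recalled: pd.DataFrame, C_nonrecalled: pd.DataFrame
                 ) -> pd.DataFrame:
    """Elementwise recalled-minus-non-recalled contrast Δ_{I→J}.

    Δ_{I→J} and Δ_{J→I} are independent quantities; no (anti)symmetry is
    implied or imposed.
    """
    if list(C_recalled.index) != list(C_nonrecalled.index) or \
            list(C_recalled.columns) != list(C_nonrecalled.columns):
        raise ValueError("mismatched region sets")
    return C_recalled - C_nonrecalled


def group_test_fdr(per_subject_deltas, min_subjects: int = 10,
                   alpha: float = 0.05) -> ConnectivityContrast:
    """One-sample two-sided t-tests per ordered region pair, BH-corrected.

    ``per_subject_deltas`` is a sequence of region × region DataFrames (NaN
    where a subject contributes no electrodes).  Diagonal cells are excluded;
    cells with fewer than ``min_subjects`` contributing subjects are excluded
    *before* the Benjamini–Hochberg adjustment.
    """
    from statsmodels.stats.multitest import multipletests
    deltas = list(per_subject_deltas)
    if not deltas:
        raise ValueError("no subjects")
    regions = list(deltas[0].index)
    arr = np.stack([d.to_numpy(dtype=float) for d in deltas])
    R = len(regions)
    tmat = np.full((R, R), np.nan)
    pmat = np.full((R, R), np.nan)
    nmat = np.zeros((R, R), dtype=int)
    mean = np.full((R, R), np.nan)
    tested = []
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            vals = arr[:, i, j]
            vals = vals[~np.isnan(vals)]
            nmat[i, j] = vals.size
            if vals.size:
                mean[i, j] = vals.mean()
            if vals.size < max(min_subjects, 2):
                continue
            sd = vals.std(ddof=1)
            if sd == 0.0:
                t = 0.0 if vals.mean() == 0.0 else np.inf * np.sign(vals.mean())
                p = 1.0 if vals.mean() == 0.0 else 0.0
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
            tmat[i, j], pmat[i, j] = t, p
            tested.append((i, j))
    padj = np.full((R, R), np.nan)
    if tested:
        raw = np.array([pmat[i, j] for i, j in tested])
        adj = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
        for (i, j), a in zip(tested, adj):
            padj[i, j] = a
    df = lambda m: pd.DataFrame(m, index=regions, columns=regions)  # noqa: E731
    return ConnectivityContrast(regions=regions, delta=df(mean),
                                per_subject=arr, t=df(tmat), p=df(pmat),
                                p_adj=df(padj), n_subjects=df(nmat))


def delta_auc_frequency_curve(auc_volatility: float,
                              auc_power_by_freq: np.ndarray,
                              freqs: np.ndarray,
                              n_eval: int = 11):
    """ΔAUC(volatility − power) as a frequency curve with a GP zero-test.

    Compares the volatility classifier's AUC against per-frequency power
    classifiers: positive values mean volatility features decode memory at
    least as well as power at that frequency.  The curve is smoothed by
    Matern(5/2) GP regression and tested against the zero function.
    """
    from .spectral import gp_regress_frequency
    delta = float(auc_volatility) - np.asarray(auc_power_by_freq, dtype=float)
    return gp_regress_frequency(np.asarray(freqs, dtype=float), delta,
                                n_eval=n_eval)


def fit_condition_contrast(epochs_recalled, epochs_nonrecalled,
                           region_labels: list[str], **mcmc_kwargs
                           ) -> pd.DataFrame:
    """Per-subject Δ network: fit the MSV model per condition, aggregate, subtract.

    Convenience wrapper for the end-to-end subsequent-memory pipeline; MCMC
    settings pass through to :func:`msvolt.mcmc.run_mcmc`.
    """
    from .mcmc import run_mcmc, posterior_summary
    nets = []
    for data in (epochs_recalled, epochs_nonrecalled):
        draws = run_mcmc(data, **mcmc_kwargs)
        params, _ = posterior_summary(draws)
        nets.append(region_connectivity(params.beta, region_labels))
    return sme_contrast(nets[0], nets[1])
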