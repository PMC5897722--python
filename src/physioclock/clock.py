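"""The transcriptomic age clock.

Three stages, all fit on control samples only:

1. *Classifier discovery* — leave-one-out rounds over the control
   samples; each round re-runs the affected-probe procedure (ANOVA + BH +
   Tukey + 1.5-fold) with age class as the factor on the retained
   samples and uses the resulting probes as k-NN features to classify
   the held-out sample.  Probes selected in 100% of rounds are the aging
   classifiers.
2. *Clock fit* — principal components of the samples x classifiers
   matrix seed a linear model of chronological age (in days); components
   enter by forward stepwise selection, accepting the move that most
   decreases AIC until none does.
3. *Prediction* — any sample's profile is centered with the training
   means, projected onto the training loadings and pushed through the
   linear model, yielding a physiological age in days and an
   acceleration percentage relative to chronological age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .diffexpr import call_affected


@dataclass
class ClassifierSet:
    table: pd.DataFrame  # selection_freq, is_classifier per probe
    loo_accuracy: float
    n_rounds: int
    failed_rounds: list = field(default_factory=list)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index[self.table["is_classifier"]]


def _knn_predict(train: np.ndarray, train_labels, query: np.ndarray, k: int):
    """Majority-vote k-NN with a distance-weighted tie break.

    ``train`` is samples x features.  Ties in vote count go to the class
    whose voters are nearest in total distance.
    """
    d = np.sqrt(((train - query[None, :]) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[:k]
    votes: dict = {}
    for i in nearest:
        lab = train_labels[i]
        cnt, dist = votes.get(lab, (0, 0.0))
        votes[lab] = (cnt + 1, dist + d[i])
    # most votes first, then smallest summed distance
    return min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1]))


def loo_knn_select(expr_controls: pd.DataFrame, ages, k: int = 3,
                   alpha: float = 0.05, fold: float = 1.5) -> ClassifierSet:
    """Leave-one-out feature-stability selection of aging classifiers.

    ``ages`` assigns each control column its age class.  Each round holds
    out one sample, calls affected probes across age classes on the rest,
    and classifies the held-out sample by k-NN on those probes.
    """
    ages = pd.Series(ages, index=expr_controls.columns) \
        if not isinstance(ages, pd.Series) else ages.loc[expr_controls.columns]
    n = expr_controls.shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    counts = pd.Series(0, index=expr_controls.index, dtype=int)
    correct, scored, failed = 0, 0, []
    for held in expr_controls.columns:
        train = expr_controls.drop(columns=held)
        try:
            de = call_affected(train, ages.drop(held).astype(str),
                               alpha=alpha, fold=fold)
        except ValueError as exc:
            raise ValueError(f"LOO round {held!r}: {exc}") from exc
        feats = de.affected_probes()
        if len(feats) == 0:
            failed.append(held)
            warnings.warn(f"LOO round holding out {held!r} selected no features")
            continue
        counts.loc[feats] += 1
        pred = _knn_predict(train.loc[feats].to_numpy(float).T,
                            ages.drop(held).astype(str).to_numpy(),
                            expr_controls.loc[feats, held].to_numpy(float), k)
        scored += 1
        if pred == str(ages[held]):
            correct += 1
    freq = counts / n
    table = pd.DataFrame({"selection_freq": freq,
                          "is_classifier": freq == 1.0})
    acc = correct / scored if scored else float("nan")
    return ClassifierSet(table=table, loo_accuracy=acc, n_rounds=n,
                         failed_rounds=failed)


@dataclass
class AgeClock:
    probe_ids: list
    center: np.ndarray          # per-probe training means
    loadings: np.ndarray        # probes x candidate PCs
    candidate_pcs: int
    selected_pcs: list          # indices into the candidate PCs
    coefficients: np.ndarray    # intercept followed by per-selected-PC weights
    aic_trace: list

    def to_json(self, path) -> None:
        payload = {
            "probe_ids": list(self.probe_ids),
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "candidate_pcs": self.candidate_pcs,
            "selected_pcs": list(self.selected_pcs),
            "coefficients": self.coefficients.tolist(),
            "aic_trace": list(self.aic_trace),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AgeClock":
        with open(path) as fh:
            d = json.load(fh)
        return cls(probe_ids=d["probe_ids"], center=np.asarray(d["center"]),
                   loadings=np.asarray(d["loadings"]),
                   candidate_pcs=d["candidate_pcs"],
                   selected_pcs=d["selected_pcs"],
                   coefficients=np.asarray(d["coefficients"]),
                   aic_trace=d["aic_trace"])


def fit_age_clock(expr_controls: pd.DataFrame, ages, classifiers,
                  var_explained: float = 0.95) -> AgeClock:
    """Fit the PC-seeded, AIC-optimized linear age model on controls.

    ``classifiers`` is a :class:`ClassifierSet` or an iterable of probe
    ids.  Candidate components are those reaching ``var_explained``
    cumulative variance, capped at ``n_samples - 2``; forward stepwise
    selection adds the component that most decreases AIC until no move
    decreases it.  The response is numeric age in days.
    """
    probe_ids = list(classifiers.probe_ids) if isinstance(classifiers, ClassifierSet) \
        else list(classifiers)
    if len(probe_ids) < 2:
        raise ValueError("need at least 2 classifier probes")
    y = np.asarray(pd.Series(ages, index=expr_controls.columns)
                   if not isinstance(ages, pd.Series)
                   else ages.loc[expr_controls.columns], dtype=float)
    if expr_controls.shape[1] < 4:
        raise ValueError("need at least 4 training samples")
    if np.unique(y).size < 3:
        raise ValueError("need at least 3 distinct training ages")

    X = expr_controls.loc[probe_ids].to_numpy(float).T  # samples x probes
    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    nonzero = var > var.sum() * 1e-12
    cumvar = np.cumsum(var[nonzero]) / var[nonzero].sum()
    n_candidate = int(np.searchsorted(cumvar, var_explained) + 1)
    n_candidate = min(n_candidate, X.shape[0] - 2, int(nonzero.sum()))
    loadings = Vt[:n_candidate].T          # probes x PCs
    scores = Xc @ loadings                 # samples x PCs

    selected: list = []
    model = sm.OLS(y, np.ones((len(y), 1))).fit()
    trace = [model.aic]
    remaining = list(range(n_candidate))
    while remaining:
        fits = []
        for j in remaining:
            cand = selected + [j]
            fit = sm.OLS(y, sm.add_constant(scores[:, cand])).fit()
            fits.append((fit.aic, j, fit))
        best_aic, best_j, best_fit = min(fits, key=lambda t: t[0])
        if best_aic >= trace[-1]:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        model = best_fit
        trace.append(best_aic)

    if selected:
        coefs = np.asarray(model.params, dtype=float)
    else:
        coefs = np.array([float(np.mean(y))])
    return AgeClock(probe_ids=probe_ids, center=center,
                    loadings=loadings, candidate_pcs=n_candidate,
                    selected_pcs=selected, coefficients=coefs,
                    aic_trace=trace)


def predict_physio_age(clock: AgeClock, expr_samples: pd.DataFrame,
                       chron_ages=None) -> pd.DataFrame:
    """Predict physiological age (days) for each sample column.

    Returns a table indexed by sample id with ``physio_age`` and, when
    chronological ages are supplied, ``chron_age`` and ``accel_pct`` =
    100 * (physio - chron) / chron.  Predictions are not clipped to the
    training age range.
    """
    missing = [p for p in clock.probe_ids if p not in expr_samples.index]
    if missing:
        raise ValueError(f"matrix lacks {len(missing)} clock probes: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    X = expr_samples.loc[list(clock.probe_ids)].to_numpy(float).T
    scores = (X - clock.center) @ clock.loadings
    if clock.selected_pcs:
        physio = clock.coefficients[0] + \
            scores[:, clock.selected_pcs] @ clock.coefficients[1:]
    else:
        physio = np.full(X.shape[0], clock.coefficients[0])
    out = pd.DataFrame({"physio_age": physio},
                       index=pd.Index(expr_samples.columns, name="sample_id"))
    if chron_ages is not None:
        chron = pd.Series(chron_ages, index=expr_samples.columns) \
            if not isinstance(chron_ages, pd.Series) \
            else chron_ages.loc[expr_samples.columns]
        out["chron_age"] = chron.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            accel = 100.0 * (out["physio_age"] - out["chron_age"]) / out["chron_age"]
        out["accel_pct"] = accel.where(out["chron_age"] > 0)
    return out


def summarize_acceleration(preds: pd.DataFrame, groups) -> dict:
    """Per-group mean +/- SEM of predictions, with ANOVA + Tukey across groups.

    ``groups`` assigns each prediction row to a group (e.g. genotype).
    With a single group only descriptives are returned.
    """
    groups = pd.Series(groups, index=preds.index) \
        if not isinstance(groups, pd.Series) else groups.loc[preds.index]
    summary: dict = {"groups": {}}
    arrays = []
    for g, sub in preds.groupby(groups):
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 predictions")
        entry = {
            "n": n,
            "physio_mean": float(sub["physio_age"].mean()),
            "physio_sem": float(sub["physio_age"].sem()),
        }
        if "accel_pct" in sub and sub["accel_pct"].notna().all():
            entry["accel_mean"] = float(sub["accel_pct"].mean())
            entry["accel_sem"] = float(sub["accel_pct"].sem())
        summary["groups"][str(g)] = entry
        arrays.append(sub["physio_age"].to_numpy(float))
    if len(arrays) > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            summary["anova_p"] = float(sps.f_oneway(*arrays).pvalue)
            tk = sps.tukey_hsd(*arrays)
        names = list(summary["groups"])
        summary["tukey_p"] = {
            f"{names[i]}|{names[j]}": float(tk.pvalue[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        }
    return summary
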