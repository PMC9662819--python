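"""Cross-protein hotspot prediction, transfer learning, and mutation-level
phenotype models.

Cross-protein prediction (CPP) trains the shallow classifier on one or
more homologs and predicts every residue of a held-out protein; the score
is the mean test F1 over independent training runs. CPP with transfer
learning (CPP_TL) additionally partitions the target protein's residues
into 10 equal subsets and, for each subset, fine-tunes the pretrained
network on that subset alone before predicting the other nine — the mean
of the 10 F1 scores is reported. Relative performance compares models
built from homology-model structures against crystal-structure models as
an F1 ratio, regressed on template identity and RMSD.

Mutation-level models score each individual substitution (e.g. from
sequence-embedding features, the 27 site features broadcast per mutant,
or their concatenation); hotspot calls then follow by ranking residues by
the percent of their mutations predicted dead and taking the top N, with
N the experimentally determined hotspot count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .gann import (ConfusionSummary, NNSpec, ShallowNet, confusion_f1,
                   resolve_combo, standardize)

logger = logging.getLogger(__name__)


@dataclass
class CppResult:
    train_ids: tuple
    test_id: str
    combo: tuple
    cpp_f1: float | None = None
    cpp_tl_f1: float | None = None
    baseline_f1: float | None = None
    run_f1s: list = field(default_factory=list)


def _pool(matrices) -> pd.DataFrame:
    if isinstance(matrices, pd.DataFrame):
        return matrices
    frames = list(matrices)
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise ValueError("feature registries differ between training matrices")
    return pd.concat(frames, ignore_index=True)


def _xy(matrix: pd.DataFrame, names) -> tuple[np.ndarray, np.ndarray]:
    return (matrix[list(names)].to_numpy(dtype=float),
            matrix["label"].to_numpy(dtype=int))


def cpp(train, test: pd.DataFrame, combo, spec: NNSpec,
        n_runs: int = 5, seed: int = 0,
        train_ids=("train",), test_id: str = "test") -> CppResult:
    """Train on the pooled training protein(s), predict all of the test protein.

    ``n_runs`` independent training runs (different weight initializations
    and shuffles) are averaged. Supports pooled multi-protein training by
    passing a list of feature matrices sharing the registry.
    """
    train_df = _pool(train)
    names = resolve_combo(train_df, combo)
    if resolve_combo(test, combo) != names:
        raise ValueError("feature registry mismatch between train and test")
    Xtr_raw, ytr = _xy(train_df, names)
    Xte_raw, yte = _xy(test, names)
    Xtr, Xte = standardize(Xtr_raw, Xte_raw)
    f1s = []
    for r in range(n_runs):
        net = ShallowNet(len(names), spec, seed=seed * 100 + r)
        net.fit(Xtr, ytr)
        f1s.append(confusion_f1(net.predict(Xte), yte).f1)
    from .gann import random_baseline
    return CppResult(
        train_ids=tuple(train_ids), test_id=test_id, combo=names,
        cpp_f1=float(np.mean(f1s)), run_f1s=f1s,
        baseline_f1=random_baseline(yte),
    )


def cpp_tl(train, test: pd.DataFrame, combo, spec: NNSpec,
           fine_tune_fraction: float = 0.1, n_partitions: int = 10,
           fine_tune_epochs: int = 1000, seed: int = 0, stratified: bool = True,
           train_ids=("train",), test_id: str = "test") -> CppResult:
    """Cross-protein prediction with transfer-learning fine-tuning.

    A network pretrained on the training protein(s) is, for each of the
    ``n_partitions`` equal subsets of the test protein, fine-tuned on that
    subset (same optimizer and learning rate, with freshly initialized
    optimizer state so the moment estimates reflect the new data) and
    scored on the remaining subsets; the mean F1 over partitions is the
    CPP_TL performance.
    """
    if not 0.0 < fine_tune_fraction < 1.0:
        raise ValueError("fine_tune_fraction must be in (0, 1) — fine-tuning on "
                         "everything leaves nothing to evaluate")
    if abs(fine_tune_fraction - 1.0 / n_partitions) > 1e-9:
        raise ValueError("fine_tune_fraction must equal 1/n_partitions")
    train_df = _pool(train)
    names = resolve_combo(train_df, combo)
    Xtr_raw, ytr = _xy(train_df, names)
    Xte_raw, yte = _xy(test, names)
    if stratified and min(np.bincount(yte, minlength=2)) < n_partitions:
        raise ValueError(
            f"test protein needs >= {n_partitions} samples per class for "
            f"{n_partitions} stratified partitions"
        )
    Xtr, Xte = standardize(Xtr_raw, Xte_raw)

    base = ShallowNet(len(names), spec, seed=seed * 100 + 7)
    base.fit(Xtr, ytr)

    for redraw in range(5):
        rs = seed * 1000 + redraw
        if stratified:
            splitter = StratifiedKFold(n_partitions, shuffle=True, random_state=rs)
            parts = [te for _, te in splitter.split(np.zeros(len(yte)), yte)]
        else:
            rng = np.random.default_rng(rs)
            order = rng.permutation(len(yte))
            parts = np.array_split(order, n_partitions)
        if all(len(np.unique(yte[p])) == 2 or not stratified for p in parts):
            break
        logger.info("re-drawing TL partition (single-class subset)")
    f1s = []
    for part in parts:
        rest = np.setdiff1d(np.arange(len(yte)), part)
        net = base.copy().reset_optimizer()
        net.fit(Xte[part], yte[part], epochs=fine_tune_epochs)
        f1s.append(confusion_f1(net.predict(Xte[rest]), yte[rest]).f1)
    from .gann import random_baseline
    return CppResult(
        train_ids=tuple(train_ids), test_id=test_id, combo=names,
        cpp_tl_f1=float(np.mean(f1s)), run_f1s=f1s,
        baseline_f1=random_baseline(yte),
    )


# ---------------------------------------------------------------------------
# Homology-model relative performance
# ---------------------------------------------------------------------------

def relative_performance(f1_model, f1_crystal, identity=None, rmsd=None) -> dict:
    """F1 ratio of homology-model-based to crystal-based models, with trends.

    ``f1_model``/``f1_crystal`` may be scalars or aligned arrays (one entry
    per template). When ``identity`` (template-target sequence identity, %)
    or ``rmsd`` (A) are given, least-squares fits of the ratio against them
    are reported with R^2.
    """
    fm = np.atleast_1d(np.asarray(f1_model, dtype=float))
    fc = np.atleast_1d(np.asarray(f1_crystal, dtype=float))
    ratio = np.full(fm.shape, np.nan)
    ok = fc != 0
    ratio[ok] = fm[ok] / fc[ok]
    out = {
        "ratio": ratio if ratio.size > 1 else float(ratio[0]),
        "ratio_percent": 100.0 * ratio if ratio.size > 1 else float(100.0 * ratio[0]),
        "undefined": bool((~ok).any()),
    }
    for name, x in (("identity", identity), ("rmsd", rmsd)):
        if x is not None:
            x = np.asarray(x, dtype=float)
            res = stats.linregress(x[ok], ratio[ok])
            out[f"vs_{name}"] = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r_squared": float(res.rvalue ** 2),
            }
    return out


# ---------------------------------------------------------------------------
# Mutation-level phenotype models and hotspot calling
# ---------------------------------------------------------------------------

def concat_mutation_features(embeddings: np.ndarray, site_features: pd.DataFrame,
                             residues) -> np.ndarray:
    """Concatenate per-mutant embedding rows with the mutated site's features."""
    emb = np.asarray(embeddings, dtype=float)
    residues = np.asarray(residues, dtype=int)
    if emb.shape[0] != residues.shape[0]:
        raise ValueError(
            f"embedding rows ({emb.shape[0]}) != mutant list length ({residues.shape[0]})"
        )
    cols = [c for c in site_features.columns if c != "label"]
    site = site_features.loc[residues, cols].to_numpy(dtype=float)
    return np.hstack([emb, site])


def mutation_phenotype_cv(X, labels, spec: NNSpec, n_repeats: int = 5,
                          k: int = 5, seed: int = 0) -> float:
    """Mean F1 of 5x fivefold CV on per-mutation feature vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels differ in length")
    f1s = []
    for rep in range(n_repeats):
        splitter = StratifiedKFold(k, shuffle=True, random_state=seed * 100 + rep)
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            Xtr, Xte = standardize(X[tr], X[te])
            net = ShallowNet(X.shape[1], spec, seed=seed * 1000 + rep * 10 + fold)
            net.fit(Xtr, y[tr])
            f1s.append(confusion_f1(net.predict(Xte), y[te]).f1)
    return float(np.mean(f1s))


@dataclass
class MutationPredictionProfile:
    """Residue-level hotspot call derived from per-mutation predictions."""

    x_percent: pd.Series          # residue -> percent of mutations predicted dead
    mean_dead_prob: pd.Series
    predicted_hotspots: frozenset
    n_top: int
    f1: float | None = None


def hotspots_from_mutations(X, labels, residues, n_top: int, spec: NNSpec,
                            true_hotspots=None, n_repeats: int = 5, k: int = 5,
                            seed: int = 0):
    """Predict hotspots by ranking residues on their predicted dead fraction.

    Residues (not mutations) are partitioned into ``k`` random folds — all
    mutations of a residue travel together, so a residue is never predicted
    by a model that saw any of its own mutations. After each repeat, every
    residue has x = percent of its mutations predicted dead; the top
    ``n_top`` residues by x (ties broken by higher mean predicted dead
    probability, then lower residue index) are the called hotspots. Returns
    (profiles per repeat, mean F1 vs ``true_hotspots`` or None).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    residues = np.asarray(residues, dtype=int)
    unique_res = np.unique(residues)
    if n_top < 1 or n_top > unique_res.size:
        raise ValueError(f"n_top must be in 1..{unique_res.size}")

    profiles, f1s = [], []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed * 100 + rep)
        order = rng.permutation(unique_res)
        parts = np.array_split(order, k)
        probs = np.full(len(y), np.nan)
        for part in parts:
            te = np.isin(residues, part)
            tr = ~te
            if len(np.unique(y[tr])) < 2:
                raise ValueError("training residues contain a single class")
            Xtr, Xte = standardize(X[tr], X[te])
            net = ShallowNet(X.shape[1], spec, seed=seed * 1000 + rep)
            net.fit(Xtr, y[tr])
            probs[te] = net.predict_proba(Xte)[:, 1]
        pred_dead = probs > 0.5
        df = pd.DataFrame({"residue": residues, "dead": pred_dead, "prob": probs})
        per_res = df.groupby("residue").agg(
            x_percent=("dead", lambda s: 100.0 * s.mean()),
            mean_prob=("prob", "mean"),
        )
        ranked = per_res.sort_values(
            ["x_percent", "mean_prob", "residue"],
            ascending=[False, False, True],
            kind="stable",
        )
        predicted = frozenset(ranked.index[:n_top].astype(int))
        profile = MutationPredictionProfile(
            x_percent=per_res["x_percent"],
            mean_dead_prob=per_res["mean_prob"],
            predicted_hotspots=predicted,
            n_top=n_top,
        )
        if true_hotspots is not None:
            truth = set(true_hotspots)
            pv = np.array([r in predicted for r in unique_res], dtype=int)
            tv = np.array([r in truth for r in unique_res], dtype=int)
            profile.f1 = confusion_f1(pv, tv).f1
            f1s.append(profile.f1)
        profiles.append(profile)
    mean_f1 = float(np.mean(f1s)) if f1s else None
    return profiles, mean_f1
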