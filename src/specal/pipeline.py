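"""End-to-end pipelines and benchmark grids.

Ties the stages together under a leakage-safe protocol: the test split is
carved out first, every fitted transform (scatter-correction reference,
smoothing, manifold embedding) is learned on the non-test samples only and
applied to the test samples afterwards, and the manifold is embedded once
before the active-learning loop, not refitted per iteration.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import active, boosting, manifold, preprocess
from .spectra_io import SpectraSet

__all__ = [
    "prepare_features",
    "preprocessing_grid",
    "learner_comparison",
    "PREPROCESS_METHODS",
]

logger = logging.getLogger(__name__)

#: Preprocessing variants of the benchmark grid: scatter correction only,
#: smoothing only, or both (the "MS" transform), each with or without the
#: manifold embedding of the result.
PREPROCESS_METHODS = ("msc", "smooth", "ms")


def prepare_features(spectra: SpectraSet, train_idx: np.ndarray,
                     method: str = "ms", embed: bool = True,
                     smooth: preprocess.SmoothSpec | None = None,
                     k: int = manifold.DEFAULT_K,
                     n_components: int | str = "auto",
                     z_range=manifold.DEFAULT_Z_RANGE,
                     on_disconnected: str = "bridge"):
    """Build the feature matrix for all samples, fitting on ``train_idx`` only.

    ``method``: ``"raw"``, ``"msc"``, ``"smooth"`` or ``"ms"``.  With
    ``embed=True`` the preprocessed training spectra are Isomap-fitted and
    every sample is projected; ``n_components="auto"`` picks Z by the
    reconstruction-RMSE scan.  Returns ``(X, info)`` where ``info`` records
    the chosen Z and RMSE curve (when embedding).
    """
    smooth = smooth or preprocess.SmoothSpec()
    train = spectra.subset(train_idx)
    info: dict = {"method": method, "embed": embed}

    if method == "raw":
        X_all = spectra.reflectance.copy()
    elif method == "msc":
        model = preprocess.msc_fit(train, reference="mean")
        X_all = preprocess.msc_apply(model, spectra.reflectance)
    elif method == "smooth":
        X_all = preprocess.moving_window_smooth(spectra.reflectance, smooth)
    elif method == "ms":
        transform = preprocess.MSTransform(smooth=smooth)
        transform.fit_transform(train)
        X_all = transform.transform(spectra.reflectance)
    else:
        raise ValueError(f"unknown preprocessing method '{method}'")

    if not embed:
        return X_all, info

    X_train = X_all[train_idx]
    z_range = list(z_range)
    z_max = (max(z_range) if n_components == "auto" else int(n_components))
    z_max = min(z_max, X_train.shape[0] - 1)
    model = manifold.isomap_fit(X_train, k=k, n_components=z_max,
                                on_disconnected=on_disconnected)
    if n_components == "auto":
        candidates = [z for z in z_range if z <= z_max]
        curve = np.array([manifold.reconstruction_rmse(model, z)
                          for z in candidates])
        best = candidates[manifold.argmin_with_ties(curve)]
        model.n_components = best
        info["rmse_curve"] = curve
        info["z_candidates"] = candidates
        logger.info("selected %d manifold components (RMSE %.4f)",
                    best, float(curve.min()))
    info["n_components"] = model.n_components

    X_embedded = np.empty((spectra.n_samples, model.n_components))
    X_embedded[train_idx] = model.embedding
    rest = np.setdiff1d(np.arange(spectra.n_samples), train_idx)
    if rest.size:
        X_embedded[rest] = manifold.isomap_transform(model, X_all[rest])
    info["isomap_model"] = model
    return X_embedded, info


def _method_grid():
    names = []
    for method in PREPROCESS_METHODS:
        names.append((f"{method.upper()}-FS", method, False))
    for method in PREPROCESS_METHODS:
        names.append((f"{method.upper()}-Isomap", method, True))
    return names


def preprocessing_grid(spectra: SpectraSet, config: active.ALConfig,
                       boost_params: boosting.BoostParams | None = None,
                       smooth: preprocess.SmoothSpec | None = None,
                       k: int = manifold.DEFAULT_K,
                       n_components: int | str = "auto") -> pd.DataFrame:
    """Uncertainty-sampling runs under each preprocessing variant.

    Rows: {MSC, SMOOTH, MS} x {full spectrum, Isomap embedding}; columns
    the mean test metrics over ``config.n_runs`` per-run pools.
    """
    y = spectra.labels
    n_classes = int(y.max()) + 1
    boost_params = boost_params or boosting.BoostParams(n_classes=n_classes)
    rows = []
    for run in range(config.n_runs):
        run_seed = int(np.random.SeedSequence(
            [config.seed, run]).generate_state(1)[0] % 2**31)
        run_config = active.ALConfig(**{**vars(config), "seed": run_seed,
                                        "batch_size": None})
        base_state = active.init_pools(y, run_config, n_classes)
        train_idx = np.sort(np.concatenate(
            [base_state.labeled_idx, base_state.unlabeled_idx]))
        for name, method, embed in _method_grid():
            X, _ = prepare_features(spectra, train_idx, method=method,
                                    embed=embed, smooth=smooth, k=k,
                                    n_components=n_components)
            params = boosting.BoostParams(**{**vars(boost_params),
                                             "n_classes": n_classes,
                                             "seed": run_seed})
            state = active.ALState(
                labeled_idx=base_state.labeled_idx.copy(),
                unlabeled_idx=base_state.unlabeled_idx.copy(),
                test_idx=base_state.test_idx.copy())
            state = active.run_eal(X, y, run_config,
                                   active.BoostLearner(params), state=state,
                                   n_classes=n_classes)
            report = state.final_report
            rows.append({"run": run, "method": name, "OA": report.oa,
                         "Kappa": report.kappa,
                         "Macro": report.macro_precision,
                         "Recall": report.macro_recall,
                         "F1": report.macro_f1})
    frame = pd.DataFrame(rows)
    order = [name for name, _, _ in _method_grid()]
    return (frame.groupby("method")[["OA", "Kappa", "Macro", "Recall", "F1"]]
            .mean().reindex(order))


def learner_comparison(spectra: SpectraSet, config: active.ALConfig,
                       boost_params: boosting.BoostParams | None = None,
                       smooth: preprocess.SmoothSpec | None = None,
                       k: int = manifold.DEFAULT_K,
                       n_components: int | str = "auto") -> pd.DataFrame:
    """Active/passive learner comparison on the MS + Isomap representation.

    The representation is fitted per run on that run's non-test samples;
    methods then share identical pools and total label counts.
    """
    y = spectra.labels
    n_classes = int(y.max()) + 1
    # features depend on the run's split, so delegate one run at a time
    frames = []
    for run in range(config.n_runs):
        run_seed = int(np.random.SeedSequence(
            [config.seed, run]).generate_state(1)[0] % 2**31)
        run_config = active.ALConfig(**{**vars(config), "seed": run_seed,
                                        "n_runs": 1, "batch_size": None})
        base_state = active.init_pools(y, run_config, n_classes)
        train_idx = np.sort(np.concatenate(
            [base_state.labeled_idx, base_state.unlabeled_idx]))
        X, _ = prepare_features(spectra, train_idx, method="ms", embed=True,
                                smooth=smooth, k=k,
                                n_components=n_components)
        frames.append(active.run_comparison(X, y, run_config, boost_params,
                                            base_state=base_state))
    stacked = pd.concat(frames)
    return stacked.groupby(level=0, sort=False).mean().reindex(
        frames[0].index)
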