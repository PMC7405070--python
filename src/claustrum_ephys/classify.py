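"""Supervised cell-type classification.

Each classification stage standardizes the features, reduces them with PCA
to the components capturing at least 99% of variance, and fits a
single-hidden-layer feedforward network (default 10 hidden units, L2 weight
decay 0.001, logistic hidden activation, softmax output, full-batch L-BFGS).
Hyperparameters can optionally be chosen by a 10-fold cross-validated grid
search (hidden units in {2, 5, 10, 20}, decay in {1e-4, 1e-3, 1e-2}).

Three stages are stacked hierarchically: interneuron vs projection neuron
(38-property set), then either the five-way PN-subtype stage (38 properties)
or the three-way IN-subtype stage (63 properties).  Final probabilities over
the eight types are products along the tree branches and sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import registry

__all__ = [
    "NeuralStageClassifier",
    "ClaustrumTypeClassifier",
    "PredictionResult",
    "fit_stage",
    "cross_validate",
    "save_model",
    "load_model",
]

PN_TYPES = ["PN1", "PN2", "PN3", "PN4", "PN5"]
IN_TYPES = ["PV", "SST", "VIP"]
ALL_TYPES = PN_TYPES + IN_TYPES

HIDDEN_GRID = (2, 5, 10, 20)
DECAY_GRID = (1e-4, 1e-3, 1e-2)


def _check_classes(y: np.ndarray, min_per_class: int = 3) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    small = classes[counts < min_per_class]
    if small.size:
        raise ValueError(f"classes with fewer than {min_per_class} members: {list(small)}")


class NeuralStageClassifier(BaseEstimator, ClassifierMixin):
    """Standardize -> PCA (>=99% variance) -> one-hidden-layer network.

    Parameters
    ----------
    hidden_units : int
        Hidden layer size (ignored when ``grid_search`` is on).
    weight_decay : float
        L2 regularization strength.
    variance_retained : float
        Fraction of training variance the PCA basis must capture.
    grid_search : bool
        Choose ``hidden_units`` and ``weight_decay`` by 10-fold CV accuracy
        over the standard grid before the final refit on all data.
    cv : int
        Number of stratified folds for the grid search.
    max_iter : int
        L-BFGS iteration cap.
    random_state : int

    Attributes
    ----------
    classes_ : ndarray of class labels
    scaler_, pca_, net_ : fitted pipeline blocks
    n_components_ : int
    retained_variance_ : float
    best_params_ : dict (present after a grid search)
    """

    def __init__(
        self,
        hidden_units: int = 10,
        weight_decay: float = 1e-3,
        variance_retained: float = 0.99,
        grid_search: bool = False,
        cv: int = 10,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.weight_decay = weight_decay
        self.variance_retained = variance_retained
        self.grid_search = grid_search
        self.cv = cv
        self.max_iter = max_iter
        self.random_state = random_state

    def _make_net(self, hidden: int, decay: float) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="lbfgs",
            alpha=decay,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        _check_classes(y)
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute before fitting")
        self.scaler_ = StandardScaler().fit(X)
        xs = self.scaler_.transform(X)
        self.pca_ = PCA(n_components=self.variance_retained, svd_solver="full").fit(xs)
        xp = self.pca_.transform(xs)
        self.n_components_ = int(self.pca_.n_components_)
        self.retained_variance_ = float(self.pca_.explained_variance_ratio_.sum())

        hidden, decay = self.hidden_units, self.weight_decay
        if self.grid_search:
            hidden, decay = self._grid_search(xp, y)
            self.best_params_ = {"hidden_units": hidden, "weight_decay": decay}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_ = self._make_net(hidden, decay).fit(xp, y)
        self.classes_ = self.net_.classes_
        return self

    def _grid_search(self, xp: np.ndarray, y: np.ndarray) -> tuple[int, float]:
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        best, best_acc = (self.hidden_units, self.weight_decay), -1.0
        self.cv_results_ = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for hidden in HIDDEN_GRID:
                for decay in DECAY_GRID:
                    pred = cross_val_predict(
                        self._make_net(hidden, decay), xp, y, cv=skf
                    )
                    acc = float(np.mean(pred == y))
                    self.cv_results_[(hidden, decay)] = acc
                    if acc > best_acc:
                        best, best_acc = (hidden, decay), acc
        return best

    def _transform(self, X) -> np.ndarray:
        return self.pca_.transform(self.scaler_.transform(np.asarray(X, float)))

    def predict(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict(self._transform(X))

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._transform(X))


def fit_stage(
    X, y, grid_search: bool = False, random_state: int = 0, **kwargs
) -> NeuralStageClassifier:
    """Fit one classification stage (thin wrapper)."""
    return NeuralStageClassifier(
        grid_search=grid_search, random_state=random_state, **kwargs
    ).fit(X, y)


def cross_validate(
    X, y, n_splits: int = 10, random_state: int = 0, **kwargs
) -> tuple[float, pd.DataFrame]:
    """Pooled stratified k-fold CV accuracy and confusion table of one stage."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    model = NeuralStageClassifier(random_state=random_state, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(model, X, y, cv=skf)
    acc = float(np.mean(pred == y))
    classes = np.unique(y)
    table = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return acc, table


@dataclass
class PredictionResult:
    """Per-stage probabilities and the final eight-way call for one cell."""

    cell_id: str
    stage_probs: dict[str, dict[str, float]]
    final_probs: dict[str, float]
    label: str

    @property
    def final_probability(self) -> float:
        return self.final_probs[self.label]


class ClaustrumTypeClassifier(BaseEstimator, ClassifierMixin):
    """Three-stage hierarchical classifier over the eight claustral types.

    Stage 1 separates interneurons from projection neurons on the
    38-property set; the PN-subtype stage (PN1..PN5) also uses the
    38-property set while the IN-subtype stage (PV/SST/VIP) uses the
    63-property set.  ``fit`` expects a DataFrame whose columns are registry
    keys and a label vector over the eight types.

    Final probabilities are branch products: P(PN_k) = P(PN) * P(PN_k | PN).
    """

    def __init__(
        self,
        hidden_units: int = 10,
        weight_decay: float = 1e-3,
        variance_retained: float = 0.99,
        grid_search: bool = False,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.weight_decay = weight_decay
        self.variance_retained = variance_retained
        self.grid_search = grid_search
        self.random_state = random_state

    def _stage(self) -> NeuralStageClassifier:
        return NeuralStageClassifier(
            hidden_units=self.hidden_units,
            weight_decay=self.weight_decay,
            variance_retained=self.variance_retained,
            grid_search=self.grid_search,
            random_state=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y, in_table: pd.DataFrame | None = None,
            in_labels=None):
        """Fit the three stages.

        ``X``/``y`` carry the whole cohort (38-property set or wider).  The
        IN-subtype stage prefers its canonical 63-property set; when a
        dedicated interneuron table is supplied via ``in_table``/
        ``in_labels`` it is trained on that, otherwise on the interneuron
        rows of ``X`` restricted to whichever of its keys are present.
        """
        y = np.asarray(y).astype(str)
        unknown = set(y) - set(ALL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
        is_in = np.isin(y, IN_TYPES)
        coarse = np.where(is_in, "IN", "PN")

        def avail(df: pd.DataFrame, keys: list[str]) -> list[str]:
            present = [k for k in keys if k in df.columns]
            if len(present) < len(keys):
                warnings.warn(
                    f"{len(keys) - len(present)} canonical features absent from "
                    "the training table; stage trained on the rest",
                    stacklevel=2,
                )
            return present

        def prep(df: pd.DataFrame, mask, keys: list[str]):
            sub = df.loc[mask, keys].astype(float)
            means = sub.mean()
            return sub.fillna(means).to_numpy(), means

        self.feature_keys_ = {
            "in_vs_pn": avail(X, registry.KEYS_38),
            "pn_subtype": avail(X, registry.KEYS_38),
        }
        self.stage_means_ = {}
        self.stages_ = {}

        x1, m1 = prep(X, np.ones(len(y), bool), self.feature_keys_["in_vs_pn"])
        self.stage_means_["in_vs_pn"] = m1
        self.stages_["in_vs_pn"] = self._stage().fit(x1, coarse)

        xpn, mpn = prep(X, ~is_in, self.feature_keys_["pn_subtype"])
        self.stage_means_["pn_subtype"] = mpn
        self.stages_["pn_subtype"] = self._stage().fit(xpn, y[~is_in])

        if in_table is not None:
            if in_labels is None:
                raise ValueError("in_table requires in_labels")
            keys_in = avail(in_table, registry.KEYS_63)
            xin, min_ = prep(in_table, np.ones(len(in_table), bool), keys_in)
            y_in = np.asarray(in_labels).astype(str)
        else:
            keys_in = avail(X, registry.KEYS_63)
            xin, min_ = prep(X, is_in, keys_in)
            y_in = y[is_in]
        self.feature_keys_["in_subtype"] = keys_in
        self.stage_means_["in_subtype"] = min_
        self.stages_["in_subtype"] = self._stage().fit(xin, y_in)

        self.classes_ = np.array(ALL_TYPES)
        return self

    def _stage_matrix(self, X: pd.DataFrame, stage: str) -> np.ndarray:
        keys = self.feature_keys_[stage]
        missing_cols = [k for k in keys if k not in X.columns]
        df = X.copy()
        for k in missing_cols:
            df[k] = np.nan
        sub = df[keys].astype(float)
        if sub.isna().all(axis=None):
            raise ValueError("feature vector is empty")
        if sub.isna().any(axis=None):
            warnings.warn("missing features imputed with stage training means", stacklevel=2)
            sub = sub.fillna(self.stage_means_[stage])
        return sub.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "stages_")
        s1 = self.stages_["in_vs_pn"]
        p1 = s1.predict_proba(self._stage_matrix(X, "in_vs_pn"))
        p_in = p1[:, list(s1.classes_).index("IN")]
        p_pn = 1.0 - p_in

        spn = self.stages_["pn_subtype"]
        ppn = spn.predict_proba(self._stage_matrix(X, "pn_subtype"))
        sin = self.stages_["in_subtype"]
        pin = sin.predict_proba(self._stage_matrix(X, "in_subtype"))

        out = np.zeros((len(X), len(ALL_TYPES)))
        for j, t in enumerate(ALL_TYPES):
            if t in PN_TYPES:
                out[:, j] = p_pn * ppn[:, list(spn.classes_).index(t)]
            else:
                out[:, j] = p_in * pin[:, list(sin.classes_).index(t)]
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        probs = self.predict_proba(X)
        # final label follows the argmax chain: branch first, then subtype
        s1 = self.stages_["in_vs_pn"]
        branch = s1.predict(self._stage_matrix(X, "in_vs_pn"))
        labels = []
        for i, b in enumerate(branch):
            types = IN_TYPES if b == "IN" else PN_TYPES
            cols = [ALL_TYPES.index(t) for t in types]
            labels.append(ALL_TYPES[cols[int(np.argmax(probs[i, cols]))]])
        return np.asarray(labels)

    def predict_coarse(self, X: pd.DataFrame) -> np.ndarray:
        """IN-vs-PN call of stage 1 only."""
        check_is_fitted(self, "stages_")
        return self.stages_["in_vs_pn"].predict(self._stage_matrix(X, "in_vs_pn"))

    def predict_result(self, X: pd.DataFrame) -> list[PredictionResult]:
        """Rich per-cell results with per-stage probability mappings."""
        probs = self.predict_proba(X)
        labels = self.predict(X)
        results = []
        cell_ids = (
            X["cell_id"].astype(str).tolist()
            if "cell_id" in X.columns
            else [str(i) for i in X.index]
        )
        stage_probs_all = {
            name: (st.predict_proba(self._stage_matrix(X, name)), st.classes_)
            for name, st in self.stages_.items()
        }
        for i, cid in enumerate(cell_ids):
            sp = {
                name: dict(zip(map(str, classes), map(float, mat[i])))
                for name, (mat, classes) in stage_probs_all.items()
            }
            results.append(
                PredictionResult(
                    cell_id=cid,
                    stage_probs=sp,
                    final_probs=dict(zip(ALL_TYPES, map(float, probs[i]))),
                    label=str(labels[i]),
                )
            )
        return results


# ---------------------------------------------------------------------------
# model persistence (versioned JSON archive; text only)

def _stage_to_dict(st: NeuralStageClassifier) -> dict:
    return {
        "params": st.get_params(),
        "classes": st.classes_.tolist(),
        "scaler_mean": st.scaler_.mean_.tolist(),
        "scaler_scale": st.scaler_.scale_.tolist(),
        "pca_components": st.pca_.components_.tolist(),
        "pca_mean": st.pca_.mean_.tolist(),
        "pca_explained_variance": st.pca_.explained_variance_.tolist(),
        "retained_variance": st.retained_variance_,
        "coefs": [w.tolist() for w in st.net_.coefs_],
        "intercepts": [b.tolist() for b in st.net_.intercepts_],
    }


def _stage_from_dict(d: dict) -> NeuralStageClassifier:
    st = NeuralStageClassifier(**d["params"])
    st.scaler_ = StandardScaler()
    st.scaler_.mean_ = np.array(d["scaler_mean"])
    st.scaler_.scale_ = np.array(d["scaler_scale"])
    st.scaler_.var_ = st.scaler_.scale_ ** 2
    st.scaler_.n_features_in_ = st.scaler_.mean_.size
    st.pca_ = PCA()
    st.pca_.components_ = np.array(d["pca_components"])
    st.pca_.mean_ = np.array(d["pca_mean"])
    st.pca_.n_components_ = st.pca_.components_.shape[0]
    st.pca_.explained_variance_ = np.array(d["pca_explained_variance"])
    st.pca_.whiten = False
    st.n_components_ = int(st.pca_.n_components_)
    st.retained_variance_ = d["retained_variance"]
    classes = np.array(d["classes"])
    coefs = [np.array(w) for w in d["coefs"]]
    net = st._make_net(d["params"]["hidden_units"], d["params"]["weight_decay"])
    # rebuild a fitted MLP skeleton
    net.classes_ = classes
    net.coefs_ = coefs
    net.intercepts_ = [np.array(b) for b in d["intercepts"]]
    net.n_layers_ = len(coefs) + 1
    net.n_outputs_ = coefs[-1].shape[1]
    net.out_activation_ = "softmax" if classes.size > 2 else "logistic"
    net._label_binarizer = _fit_binarizer(classes)
    net.n_features_in_ = coefs[0].shape[0]
    st.net_ = net
    st.classes_ = classes
    return st


def _fit_binarizer(classes: np.ndarray):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb


def save_model(model: ClaustrumTypeClassifier, path: str | Path) -> None:
    """Write a fitted hierarchical classifier to a versioned JSON archive."""
    check_is_fitted(model, "stages_")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format": "claustrum-ephys-model",
        "registry_version": registry.REGISTRY_VERSION,
        "params": model.get_params(),
        "feature_keys": model.feature_keys_,
        "stage_means": {k: v.to_dict() for k, v in model.stage_means_.items()},
        "stages": {k: _stage_to_dict(v) for k, v in model.stages_.items()},
    }
    path.write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> ClaustrumTypeClassifier:
    """Load a model archive; rejects registry-version mismatches."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model archive: {exc}") from exc
    if payload.get("format") != "claustrum-ephys-model":
        raise ValueError("not a claustrum-ephys model archive")
    if payload["registry_version"] != registry.REGISTRY_VERSION:
        raise ValueError(
            f"registry version mismatch: archive {payload['registry_version']}, "
            f"installed {registry.REGISTRY_VERSION}"
        )
    model = ClaustrumTypeClassifier(**payload["params"])
    model.feature_keys_ = payload["feature_keys"]
    model.stage_means_ = {k: pd.Series(v) for k, v in payload["stage_means"].items()}
    model.stages_ = {k: _stage_from_dict(v) for k, v in payload["stages"].items()}
    model.classes_ = np.array(ALL_TYPES)
    return model
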