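"""Neural-embedding of patients and the Pan-Myeloid Axis.

A feed-forward diagnosis classifier (input 339 -> 100 ReLU -> 65 ReLU ->
8 softmax) is trained to predict the diagnosis from the phenogenetic
feature vector.  Its last hidden layer is a learned 65-dimensional
nonlinear representation of each patient; principal component analysis of
that representation embeds the cohort in two dimensions.  Patients with a
myeloid diagnosis (AML, MDS, MDS/MPN, MPN) are then projected onto the
first principal direction of the myeloid subset of the 2-D embedding --
the *Pan-Myeloid Axis* -- oriented so that AML sits to the right of MDS.

Aberrations are placed on the axis by the centroid of their carriers;
phenotype features by a carrier-value-weighted mean of patient positions.
Order stability is assessed by stratified bootstrap and pairwise Kendall
rank correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .cohort import PatientRecord, feature_matrix
from .schema import FeatureSchema, MYELOID_DIAGNOSES


@dataclass(frozen=True)
class NetConfig:
    """Training hyperparameters for the diagnosis classifier.

    The layer widths are the model; the optimizer settings are ordinary
    choices (adaptive-moment gradient descent on cross-entropy with early
    stopping on a 10% validation split) and are all configurable.
    """

    hidden: tuple[int, int] = (100, 65)
    learning_rate: float = 1e-3
    max_iter: int = 200
    early_stopping: bool = True
    validation_fraction: float = 0.1
    alpha: float = 1e-4  # L2 penalty


@dataclass
class DiagnosisNet:
    """A fitted classifier plus the feature standardization it was fit with."""

    model: MLPClassifier
    scaler: StandardScaler
    continuous_idx: np.ndarray
    n_features: int

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    @property
    def hidden_widths(self) -> tuple[int, int]:
        return tuple(self.model.hidden_layer_sizes)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        X = X.copy()
        X[:, self.continuous_idx] = self.scaler.transform(X[:, self.continuous_idx])
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self._prepare(X))


def _continuous_indices(schema: FeatureSchema) -> np.ndarray:
    names = schema.names
    cont = set(schema.continuous)
    return np.array([i for i, n in enumerate(names) if n in cont])


def _make_mlp(config: NetConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=config.hidden,
        activation="relu",
        solver="adam",
        alpha=config.alpha,
        learning_rate_init=config.learning_rate,
        max_iter=config.max_iter,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=10,
        random_state=seed,
    )


def train_classifier(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[str],
    schema: FeatureSchema,
    folds: int = 5,
    seed: int = 0,
    config: NetConfig = NetConfig(),
) -> tuple[DiagnosisNet, dict[str, float], float]:
    """Cross-validate and fit the diagnosis classifier.

    Returns the model refit on the full cohort, the per-class one-vs-rest
    AUROC from out-of-fold predicted probabilities, and their class-size
    weighted mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two diagnosis classes")
    small = [c for c, n in zip(classes, counts) if n < folds]
    if small:
        raise ValueError(
            f"classes with fewer members than folds ({folds}): {small}"
        )
    cont_idx = _continuous_indices(schema)

    oof = np.zeros((len(y), len(classes)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at capped epochs
        for fold, (train, test) in enumerate(skf.split(X, y)):
            net = _fit_net(X[train], y[train], cont_idx, config, seed + fold)
            proba = net.predict_proba(X[test])
            # align fold class order to the global class order
            col = {c: k for k, c in enumerate(net.classes_)}
            for k, c in enumerate(classes):
                if c in col:
                    oof[test, k] = proba[:, col[c]]
        final = _fit_net(X, y, cont_idx, config, seed)

    per_class: dict[str, float] = {}
    for k, c in enumerate(classes):
        per_class[str(c)] = float(roc_auc_score((y == c).astype(int), oof[:, k]))
    weighted = float(np.average([per_class[str(c)] for c in classes], weights=counts))
    return final, per_class, weighted


def _fit_net(X, y, cont_idx, config, seed) -> DiagnosisNet:
    scaler = StandardScaler().fit(X[:, cont_idx])
    Xs = X.copy()
    Xs[:, cont_idx] = scaler.transform(X[:, cont_idx])
    model = _make_mlp(config, seed).fit(Xs, y)
    return DiagnosisNet(
        model=model, scaler=scaler, continuous_idx=cont_idx, n_features=X.shape[1]
    )


def hidden_representation(net: DiagnosisNet, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Last-hidden-layer activations (65-dim, all >= 0 by rectification)."""
    Xs = net._prepare(np.asarray(X, dtype=float))
    h = Xs
    # forward pass through all hidden layers; output layer excluded
    for W, b in zip(net.model.coefs_[:-1], net.model.intercepts_[:-1]):
        h = np.maximum(h @ W + b, 0.0)
    return h


def embed_2d(H: np.ndarray) -> np.ndarray:
    """First two principal components of the hidden representation.

    The sign of each component is fixed so that the largest-magnitude
    loading is positive, making the embedding reproducible across linear
    algebra backends.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] < 3:
        raise ValueError("need at least three patients for a 2-D embedding")
    pca = PCA(n_components=2, svd_solver="full", random_state=0)
    coords = pca.fit_transform(H)
    for k in range(2):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def pan_myeloid_axis(
    coords2d: np.ndarray,
    diagnoses: Sequence[str],
    fallback_sign: float = 1.0,
) -> pd.Series:
    """Project myeloid patients onto the one-dimensional Pan-Myeloid Axis.

    Positions are the projection of the myeloid patients' 2-D coordinates
    onto the first principal direction of the myeloid subset, oriented so
    that mean(AML) > mean(MDS) ("right" = AML-ish).  Returns a Series
    indexed by the *positional* index of the myeloid patients.
    """
    coords2d = np.asarray(coords2d, dtype=float)
    diagnoses = np.asarray(diagnoses)
    mask = np.isin(diagnoses, MYELOID_DIAGNOSES)
    idx = np.flatnonzero(mask)
    sub = coords2d[mask]
    if len(sub) < 2 or len(set(diagnoses[mask])) < 2:
        raise ValueError("need >= 2 myeloid patients spanning >= 2 diagnoses")
    centered = sub - sub.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    positions = centered @ vt[0]
    dx = diagnoses[mask]
    if "AML" in dx and "MDS" in dx:
        if positions[dx == "AML"].mean() < positions[dx == "MDS"].mean():
            positions = -positions
    else:
        warnings.warn(
            "cohort lacks AML or MDS patients; axis orientation falls back "
            "to the configured sign",
            stacklevel=2,
        )
        positions = positions * np.sign(fallback_sign)
    return pd.Series(positions, index=idx, name="axis")


def aberration_centroids(
    positions: pd.Series | np.ndarray,
    carriers: pd.DataFrame,
) -> pd.Series:
    """Unweighted mean position of each aberration's carriers.

    ``carriers`` is a 0/1 patient x aberration matrix aligned row-wise to
    ``positions``.  Aberrations without carriers are excluded with a
    warning.
    """
    pos = np.asarray(positions, dtype=float)
    out = {}
    skipped = []
    for ab in carriers.columns:
        mask = carriers[ab].to_numpy().astype(bool)
        if not mask.any():
            skipped.append(ab)
            continue
        out[ab] = float(pos[mask].mean())
    if skipped:
        warnings.warn(
            f"aberrations without carriers excluded from centroids: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    return pd.Series(out, name="centroid")


def feature_axis_positions(
    positions: pd.Series | np.ndarray, features: pd.DataFrame
) -> pd.Series:
    """Axis position of each phenotype feature.

    Each feature is min-max scaled to [0, 1] over the embedded patients
    and used as weights in a weighted mean of patient positions, placing
    a feature where its high values concentrate.  Constant features are
    excluded.
    """
    pos = np.asarray(positions, dtype=float)
    out = {}
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        lo, hi = np.nanmin(v), np.nanmax(v)
        if not np.isfinite(lo) or hi - lo <= 0:
            continue
        w = (v - lo) / (hi - lo)
        if w.sum() <= 0:
            continue
        out[name] = float(np.average(pos, weights=w))
    return pd.Series(out, name="feature_axis")


def order_along_axis(positions: Mapping[str, float] | pd.Series) -> list[str]:
    """Ascending order along the axis, ties broken alphabetically."""
    items = dict(positions)
    return sorted(items, key=lambda name: (items[name], name))


# ---------------------------------------------------------------------------
# end-to-end axis pipeline and bootstrap stability


@dataclass
class AxisEmbedding:
    """Full embedding result for one cohort."""

    patient_ids: tuple[str, ...]
    diagnoses: tuple[str, ...]
    coords2d: np.ndarray
    axis: pd.Series  # positional index into patient_ids (myeloid only)
    gene_positions: pd.Series
    feature_positions: pd.Series
    weighted_auroc: float | None = None
    per_class_auroc: dict[str, float] = field(default_factory=dict)

    @property
    def myeloid_patient_ids(self) -> list[str]:
        return [self.patient_ids[i] for i in self.axis.index]

    def patient_order(self) -> list[str]:
        pos = dict(zip(self.myeloid_patient_ids, self.axis.to_numpy()))
        return order_along_axis(pos)

    def gene_order(self) -> list[str]:
        return order_along_axis(self.gene_positions)

    def feature_order(self) -> list[str]:
        return order_along_axis(self.feature_positions)

    def coords_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords2d, columns=["pc1", "pc2"],
            index=pd.Index(self.patient_ids, name="patient_id"),
        )
        df["diagnosis"] = self.diagnoses
        axis = pd.Series(np.nan, index=df.index)
        axis.iloc[self.axis.index] = self.axis.to_numpy()
        df["axis"] = axis
        return df


def axis_pipeline(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    seed: int = 0,
    config: NetConfig = NetConfig(),
    folds: int | None = None,
) -> AxisEmbedding:
    """Run classifier -> hidden layer -> PCA -> axis -> orderings.

    ``folds`` enables cross-validated AUROC reporting (slower); when
    ``None`` the classifier is fit once on the full cohort.
    """
    X, _ = feature_matrix(records, schema)
    y = np.array([r.diagnosis for r in records])
    cont_idx = _continuous_indices(schema)
    if folds:
        net, per_class, weighted = train_classifier(
            X.to_numpy(), y, schema, folds=folds, seed=seed, config=config
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = _fit_net(X.to_numpy(), y, cont_idx, config, seed)
        per_class, weighted = {}, None
    H = hidden_representation(net, X.to_numpy())
    coords = embed_2d(H)
    axis = pan_myeloid_axis(coords, y)

    myeloid_idx = axis.index.to_numpy()
    gene_cols = list(schema.gene_variables)
    carriers = X.iloc[myeloid_idx][gene_cols]
    carriers = carriers.loc[:, carriers.sum(axis=0) > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gene_pos = aberration_centroids(axis.to_numpy(), carriers)
    feat_cols = list(schema.continuous)
    feature_pos = feature_axis_positions(axis.to_numpy(), X.iloc[myeloid_idx][feat_cols])
    return AxisEmbedding(
        patient_ids=tuple(r.patient_id for r in records),
        diagnoses=tuple(y),
        coords2d=coords,
        axis=axis,
        gene_positions=gene_pos,
        feature_positions=feature_pos,
        weighted_auroc=weighted,
        per_class_auroc=per_class,
    )


@dataclass
class StabilityReport:
    """Pairwise Kendall taus over bootstrap replicates per order type."""

    B: int
    taus: dict[str, np.ndarray]

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind, values in self.taus.items():
            values = values[np.isfinite(values)]
            rows.append(
                {
                    "order": kind,
                    "n_pairs": len(values),
                    "mean_tau": float(np.mean(values)) if len(values) else np.nan,
                    "ci_low": float(np.percentile(values, 2.5)) if len(values) else np.nan,
                    "ci_high": float(np.percentile(values, 97.5)) if len(values) else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _pairwise_taus(position_maps: list[dict[str, float]]) -> np.ndarray:
    B = len(position_maps)
    taus = []
    for a in range(B):
        for b in range(a + 1, B):
            shared = sorted(set(position_maps[a]) & set(position_maps[b]))
            if len(shared) < 2:
                taus.append(np.nan)
                continue
            xa = [position_maps[a][s] for s in shared]
            xb = [position_maps[b][s] for s in shared]
            taus.append(kendalltau(xa, xb).statistic)
    return np.asarray(taus, dtype=float)


def bootstrap_stability(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    B: int = 100,
    seed: int = 0,
    config: NetConfig = NetConfig(),
    resample: bool = True,
) -> StabilityReport:
    """Bootstrap the axis pipeline and measure order stability.

    Draws ``B`` diagnosis-stratified resamples with replacement, reruns
    the full embedding on each, and computes Kendall tau between every
    pair of replicates for the patient, gene and feature orders (on the
    items shared by the pair).  ``resample=False`` reruns on the original
    cohort (useful as a determinism check: all taus are then 1).
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    rng = np.random.default_rng(seed)
    by_dx: dict[str, list[PatientRecord]] = {}
    for r in records:
        by_dx.setdefault(r.diagnosis, []).append(r)

    gene_maps, feat_maps, patient_maps = [], [], []
    for b in range(B):
        if resample:
            sample: list[PatientRecord] = []
            for dx, group in by_dx.items():
                picks = rng.integers(0, len(group), size=len(group))
                sample.extend(group[i] for i in picks)
        else:
            sample = list(records)
        # without resampling replicates are identical reruns (all taus 1)
        rep_seed = (seed * 1000 + b) % (2**31) if resample else seed
        emb = axis_pipeline(sample, schema, seed=rep_seed, config=config)
        gene_maps.append(dict(emb.gene_positions))
        feat_maps.append(dict(emb.feature_positions))
        pat_positions: dict[str, float] = {}
        for pid, pos in zip(emb.myeloid_patient_ids, emb.axis.to_numpy()):
            pat_positions.setdefault(pid, float(pos))
        patient_maps.append(pat_positions)

    return StabilityReport(
        B=B,
        taus={
            "patients": _pairwise_taus(patient_maps),
            "genes": _pairwise_taus(gene_maps),
            "features": _pairwise_taus(feat_maps),
        },
    )
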