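"""Dirichlet-process Beta-Binomial clustering of aberration prevalence spectra.

Genetic aberrations (gene mutations or karyotype abnormalities) are
clustered by their *prevalence spectrum* across diseases.  For aberration
``i`` and disease ``j`` the data are the carrier count ``m_ij`` out of
``n_j`` patients.  Aberrations in cluster ``k`` share a latent per-disease
prevalence ``theta_jk``; carrier counts are Binomial::

    m_ij | C_i = k  ~  Binomial(n_j, theta_jk)
    theta_jk       ~  Beta(a0, b0)            independently over j, k
    C_1..C_p       ~  Chinese restaurant process with concentration alpha

Inference is a two-step Gibbs sampler: label updates under the CRP with
the new-cluster weight collapsed to the Beta-Binomial marginal, then
conjugate Beta draws for every cluster's prevalences.  The chain is
initialized with every aberration in its own cluster.  All likelihoods
are accumulated in log space and normalized with log-sum-exp.

The concentration defaults to ``alpha = 1e-4``, which strongly favours
merging aberrations whose spectra are statistically indistinguishable;
the Beta prior defaults to the uniform ``Beta(1, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from .cohort import PatientRecord
from .schema import DIAGNOSES


@dataclass
class PrevalenceMatrix:
    """Carrier counts ``m`` (p aberrations x q diseases) with totals ``n``."""

    aberration_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    m: np.ndarray  # (p, q) int
    n: np.ndarray  # (q,) int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        p, q = self.m.shape
        if p != len(self.aberration_ids) or q != len(self.disease_ids):
            raise ValueError("matrix shape does not match id lists")
        if p < 1 or q < 1:
            raise ValueError("need at least one aberration and one disease")
        if np.any(self.n <= 0):
            bad = [d for d, t in zip(self.disease_ids, self.n) if t <= 0]
            raise ValueError(f"diseases with no patients: {bad}")
        if np.any(self.m < 0) or np.any(self.m > self.n[None, :]):
            raise ValueError("carrier counts must satisfy 0 <= m_ij <= n_j")

    @property
    def p(self) -> int:
        return self.m.shape[0]

    @property
    def q(self) -> int:
        return self.m.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.m, index=self.aberration_ids, columns=self.disease_ids)
        df.loc["__total__"] = self.n
        df.to_csv(path, sep="\t", index_label="aberration")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrevalenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="aberration")
        n = df.loc["__total__"].to_numpy()
        df = df.drop(index="__total__")
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(), n)


def build_prevalence_matrix(
    cohort: Sequence[PatientRecord],
    aberrations: Sequence[str],
    diseases: Sequence[str] = DIAGNOSES,
) -> PrevalenceMatrix:
    """Count carriers of each aberration per disease.

    An aberration id that names a karyotype flag is looked up in the
    patient's flags; any other id is treated as a gene variable.
    """
    diseases = tuple(diseases)
    n = np.array([sum(r.diagnosis == d for r in cohort) for d in diseases])
    zero = [d for d, t in zip(diseases, n) if t == 0]
    if zero:
        raise ValueError(f"diseases with no patients in cohort: {zero}")
    m = np.zeros((len(aberrations), len(diseases)), dtype=np.int64)
    disease_index = {d: j for j, d in enumerate(diseases)}
    for r in cohort:
        j = disease_index.get(r.diagnosis)
        if j is None:
            continue
        carried = r.gene_variables
        for i, aberration in enumerate(aberrations):
            if aberration in r.karyotype_flags:
                if r.karyotype_flags[aberration]:
                    m[i, j] += 1
            elif aberration in carried:
                m[i, j] += 1
    return PrevalenceMatrix(tuple(aberrations), diseases, m, n)


# ---------------------------------------------------------------------------
# sampler state


@dataclass
class DPState:
    """Mutable sampler state: labels, cluster sizes and prevalences."""

    labels: np.ndarray  # (p,) int cluster keys
    thetas: dict[int, np.ndarray]  # key -> (q,) prevalences
    alpha: float = 1e-4
    beta_prior: tuple[float, float] = (1.0, 1.0)
    _next_key: int = 0

    @property
    def cluster_sizes(self) -> dict[int, int]:
        keys, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(keys.tolist(), counts.tolist()))

    def check(self) -> None:
        sizes = self.cluster_sizes
        assert sum(sizes.values()) == len(self.labels)
        assert set(sizes) == set(self.thetas)


def sample_theta(
    members: np.ndarray,
    M: PrevalenceMatrix,
    rng: np.random.Generator,
    beta_prior: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Conjugate Beta draw of a cluster's per-disease prevalences.

    ``theta_j ~ Beta(a0 + sum_i m_ij, b0 + sum_i (n_j - m_ij))`` over the
    cluster members; an empty member set draws from the prior.
    """
    a0, b0 = beta_prior
    if len(members) == 0:
        return rng.beta(a0, b0, size=M.q)
    m_sum = M.m[members].sum(axis=0)
    fail = (M.n[None, :] - M.m[members]).sum(axis=0)
    return rng.beta(a0 + m_sum, b0 + fail)


def _new_cluster_logmarginals(M: PrevalenceMatrix, beta_prior) -> np.ndarray:
    """Per-aberration collapsed Beta-Binomial log marginal (coef dropped).

    The binomial coefficient is identical across candidate clusters for a
    fixed aberration, so it cancels in the label-update normalization and
    is omitted from both the existing- and new-cluster weights.
    """
    a0, b0 = beta_prior
    return (
        betaln(a0 + M.m, b0 + (M.n[None, :] - M.m)) - betaln(a0, b0)
    ).sum(axis=1)


def label_conditional(
    i: int,
    state: DPState,
    M: PrevalenceMatrix,
    new_logmarginal: float | None = None,
) -> tuple[list[int], np.ndarray]:
    """Full conditional of aberration ``i``'s label given the rest.

    Returns the candidate cluster keys (existing clusters, with ``i``
    removed from its own, in sorted key order) plus a trailing ``-1`` for
    a new cluster, and the normalized probability vector over them.
    """
    if new_logmarginal is None:
        new_logmarginal = float(_new_cluster_logmarginals(M, state.beta_prior)[i])
    sizes = state.cluster_sizes
    sizes[state.labels[i]] -= 1
    keys = sorted(k for k in sizes if sizes[k] > 0)
    m_i = M.m[i]
    n_minus = M.n - m_i
    logw = np.empty(len(keys) + 1)
    for idx, k in enumerate(keys):
        theta = state.thetas[k]
        loglik = float(m_i @ np.log(theta) + n_minus @ np.log1p(-theta))
        logw[idx] = np.log(sizes[k]) + loglik
    logw[-1] = np.log(state.alpha) + new_logmarginal
    probs = np.exp(logw - logsumexp(logw))
    return keys + [-1], probs / probs.sum()


@dataclass
class PosteriorSummary:
    """Retained partitions with their co-assignment consensus."""

    aberration_ids: tuple[str, ...]
    partitions: np.ndarray  # (n_samples, p) relabelled cluster ids
    coassignment: np.ndarray  # (p, p) in [0, 1]
    consensus_labels: np.ndarray  # (p,) ints 0..K-1
    modal_probability: np.ndarray  # (p,) co-assignment support
    n_clusters: np.ndarray = field(default=None)  # per retained sweep

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aberration": self.aberration_ids,
                "cluster": self.consensus_labels,
                "posterior": self.modal_probability,
            }
        )


def run_gibbs(
    M: PrevalenceMatrix,
    alpha: float = 1e-4,
    burn_in: int = 5000,
    n_samples: int = 500,
    seed: int | None = None,
    beta_prior: tuple[float, float] = (1.0, 1.0),
) -> PosteriorSummary:
    """Fit the DP Beta-Binomial mixture by Gibbs sampling.

    Alternates a full sweep of label updates with conjugate prevalence
    draws; retains ``n_samples`` unthinned partitions after ``burn_in``
    sweeps and summarizes them by the pairwise co-assignment matrix and
    the Binder-loss consensus partition.
    """
    if alpha <= 0:
        raise ValueError("concentration alpha must be > 0")
    rng = np.random.default_rng(seed)
    p = M.p
    new_logmarg = _new_cluster_logmarginals(M, beta_prior)

    # initialization: every aberration its own standalone cluster
    labels = np.arange(p, dtype=np.int64)
    thetas = {
        int(i): sample_theta(np.array([i]), M, rng, beta_prior) for i in range(p)
    }
    sizes = {int(i): 1 for i in range(p)}
    next_key = p

    retained = np.empty((n_samples, p), dtype=np.int64)
    n_clusters = np.empty(n_samples, dtype=np.int64)

    log_alpha = np.log(alpha)
    for sweep in range(burn_in + n_samples):
        # --- label updates
        for i in range(p):
            old = int(labels[i])
            sizes[old] -= 1
            if sizes[old] == 0:
                del sizes[old], thetas[old]
            keys = list(sizes)
            theta_stack = np.stack([thetas[k] for k in keys])  # (K, q)
            m_i = M.m[i]
            n_minus = M.n - m_i
            loglik = np.log(theta_stack) @ m_i + np.log1p(-theta_stack) @ n_minus
            logw = np.concatenate(
                [np.log([sizes[k] for k in keys]) + loglik,
                 [log_alpha + new_logmarg[i]]]
            )
            probs = np.exp(logw - logsumexp(logw))
            probs /= probs.sum()
            choice = rng.choice(len(keys) + 1, p=probs)
            if choice == len(keys):
                key = next_key
                next_key += 1
                sizes[key] = 1
                thetas[key] = sample_theta(np.array([i]), M, rng, beta_prior)
            else:
                key = keys[choice]
                sizes[key] += 1
            labels[i] = key
        # --- prevalence updates
        for k in list(sizes):
            members = np.flatnonzero(labels == k)
            thetas[k] = sample_theta(members, M, rng, beta_prior)
        if sweep >= burn_in:
            idx = sweep - burn_in
            retained[idx] = _canonical(labels)
            n_clusters[idx] = len(sizes)

    coassign = _coassignment(retained)
    consensus, modal = consensus_partition(retained, coassign)
    return PosteriorSummary(
        aberration_ids=M.aberration_ids,
        partitions=retained,
        coassignment=coassign,
        consensus_labels=consensus,
        modal_probability=modal,
        n_clusters=n_clusters,
    )


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for idx, lab in enumerate(labels):
        out[idx] = mapping.setdefault(int(lab), len(mapping))
    return out


def _coassignment(partitions: np.ndarray) -> np.ndarray:
    n_samples, p = partitions.shape
    co = np.zeros((p, p))
    for sample in partitions:
        co += sample[:, None] == sample[None, :]
    co /= n_samples
    np.fill_diagonal(co, 1.0)
    return co


def consensus_partition(
    partitions: np.ndarray, coassignment: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binder-loss consensus over sampled partitions.

    Selects the retained partition minimizing the Binder loss against the
    co-assignment matrix; the per-aberration posterior support is the mean
    co-assignment of each aberration with its consensus block.
    """
    partitions = np.atleast_2d(np.asarray(partitions))
    if partitions.shape[0] < 1:
        raise ValueError("need at least one sampled partition")
    if coassignment is None:
        coassignment = _coassignment(partitions)
    best_loss = np.inf
    best = partitions[0]
    iu = np.triu_indices(partitions.shape[1], k=1)
    for sample in partitions:
        same = (sample[:, None] == sample[None, :]).astype(float)
        loss = float(np.sum((same[iu] - coassignment[iu]) ** 2))
        if loss < best_loss - 1e-12:
            best_loss = loss
            best = sample
    consensus = _canonical(best)
    modal = np.empty(len(consensus))
    for i in range(len(consensus)):
        block = np.flatnonzero(consensus == consensus[i])
        modal[i] = float(coassignment[i, block].mean())
    return consensus, modal


def exact_two_aberration_posterior(
    M: PrevalenceMatrix, alpha: float, beta_prior: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Exact posterior probability that two aberrations share a cluster.

    For ``p = 2`` there are only two partitions; their posterior odds are
    the CRP prior odds ``1 : alpha`` times the ratio of Beta-Binomial
    marginal likelihoods.  Used as an independent oracle for the sampler.
    """
    if M.p != 2:
        raise ValueError("closed form requires exactly two aberrations")
    a0, b0 = beta_prior
    m, n = M.m, M.n
    joint = np.sum(
        betaln(a0 + m[0] + m[1], b0 + 2 * n - m[0] - m[1]) - betaln(a0, b0)
    )
    separate = np.sum(
        betaln(a0 + m[0], b0 + n - m[0]) - betaln(a0, b0)
    ) + np.sum(betaln(a0 + m[1], b0 + n - m[1]) - betaln(a0, b0))
    log_together = joint  # CRP prior weight 1
    log_apart = np.log(alpha) + separate
    return float(np.exp(log_together - np.logaddexp(log_together, log_apart)))
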