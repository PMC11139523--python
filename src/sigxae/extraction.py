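"""De novo signature extraction: bootstrap augmentation, multi-start
training, matched consensus clustering and model selection.

The number of active signatures K* is chosen by a stability criterion in
the NMFk tradition:

1. the catalogue is augmented by multinomial bootstrap (each genome is
   resampled t times from Multinomial(N_g, p_g));
2. for every candidate k the autoencoder is trained n times from different
   random initializations on the augmented data, and each run's decoder
   matrix and reconstruction error on the *original* catalogue are kept;
3. the n x k signature estimates are grouped into k clusters of exactly n
   members by an iterative K-means-with-matching procedure: each run's k
   columns are matched to the current centroids by solving a linear
   assignment problem (Jonker-Volgenant) on 1 - cosine similarity;
4. solutions whose consensus clusters are not compact (average or minimum
   silhouette at or below the user thresholds) are discarded;
5. among the survivors, K* is the k with the smallest mean reconstruction
   error (ties towards smaller k).

The module exposes both the individual algorithm steps and a model-object
interface: ``DeNovoSignatureModel(catalogue, config).fit()`` returns an
:class:`ExtractionResult` with the consensus signatures, the per-k
diagnostics table and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples
from sklearn.metrics.pairwise import cosine_distances

from .autoencoder import (
    PoissonMinVolumeAutoencoder,
    XAEConfig,
    XAETrainingError,
    reconstruction_error,
)
from .catalogue import SBSCatalogue, SignatureMatrix

__all__ = [
    "ExtractionConfig",
    "RunWeights",
    "ConsensusSolution",
    "ExtractionResult",
    "DeNovoSignatureModel",
    "bootstrap_augment",
    "run_batch",
    "cluster_with_matching",
    "select_optimal",
    "extract",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def _derive_seed(*entropy: int) -> int:
    """Deterministic child seed below 2**31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % _SEED_MOD)


def _default_xae() -> XAEConfig:
    return XAEConfig(latent_dim=1)


@dataclass
class ExtractionConfig:
    """Settings of the full de novo extraction procedure.

    ``t`` is the bootstrap augmentation factor, ``n`` the number of training
    repetitions per candidate k, ``k_range`` the inclusive candidate
    interval, and ``th_avg`` / ``th_min`` the silhouette stability
    thresholds.  ``xae`` is the autoencoder hyperparameter template; its
    ``latent_dim`` and ``seed`` are overwritten per candidate and per run.
    """

    t: int = 100
    n: int = 100
    k_range: tuple[int, int] = (1, 25)
    th_avg: float = 0.9
    th_min: float = 0.7
    base_seed: int = 0
    xae: XAEConfig = field(default_factory=_default_xae)

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("augmentation factor t must be >= 1")
        if self.n < 2:
            raise ValueError("need n >= 2 repetitions per k")
        k_min, k_max = self.k_range
        if k_min < 1 or k_max < k_min:
            raise ValueError(f"invalid k_range {self.k_range}")
        if not -1 <= self.th_min <= self.th_avg <= 1:
            raise ValueError("need -1 <= th_min <= th_avg <= 1")

    @classmethod
    def fast_profile(cls, **overrides) -> "ExtractionConfig":
        """Desk-scale profile: t=10, n=15, k in 1..8, short training runs."""
        defaults = dict(
            t=10, n=15, k_range=(1, 8),
            xae=XAEConfig(
                latent_dim=1, batch_size=256, learning_rate=7e-3,
                max_epochs=120, patience=30, validation_fraction=0.1,
                latent_batchnorm=True, decoder_warm_start="nmf",
                decoder_freeze_epochs=30,
            ),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class RunWeights:
    """Decoder weights and reconstruction error of one training run."""

    k: int
    run_index: int
    W: np.ndarray  # 96 x k, raw non-negative decoder weights
    W_normalized: np.ndarray  # columns scaled to unit L2 norm
    erec: float  # Frobenius error on the original catalogue
    seed: int
    failed: bool = False


@dataclass
class ConsensusSolution:
    """Consensus signatures and stability diagnostics for one k."""

    k: int
    signatures: SignatureMatrix  # normalized centroids (columns sum to 1)
    silhouette_avg: float
    silhouette_min: float
    mean_erec: float
    run_erecs: list[float]
    membership: pd.DataFrame  # run, column, cluster


@dataclass
class ExtractionResult:
    """Outcome of de novo extraction (the fitted-model results object)."""

    selected_k: int
    signatures: SignatureMatrix
    solutions: dict[int, ConsensusSolution]
    stable: bool  # False when no k passed the silhouette filter
    th_avg: float
    th_min: float
    config: ExtractionConfig | None = None

    @property
    def table(self) -> pd.DataFrame:
        """Per-k diagnostics: silhouettes, mean error, filter outcome."""
        rows = []
        for k in sorted(self.solutions):
            s = self.solutions[k]
            rows.append({
                "k": k,
                "silhouette_avg": s.silhouette_avg,
                "silhouette_min": s.silhouette_min,
                "mean_erec": s.mean_erec,
                "passes_filter": (s.silhouette_avg > self.th_avg
                                  and s.silhouette_min > self.th_min),
                "selected": k == self.selected_k,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["De novo signature extraction", "=" * 30]
        lines.append(
            self.table.to_string(
                index=False,
                formatters={
                    "silhouette_avg": "{:.4f}".format,
                    "silhouette_min": "{:.4f}".format,
                    "mean_erec": "{:.2f}".format,
                },
            )
        )
        status = "stable" if self.stable else "NO stable solution (fallback)"
        lines.append(f"Selected K* = {self.selected_k} ({status}; "
                     f"thresholds avg>{self.th_avg}, min>{self.th_min})")
        return "\n".join(lines)

    def plot_signatures(self, axes=None):
        """Bar plots of the selected consensus signatures."""
        from .plotting import plot_signatures
        return plot_signatures(self.signatures, axes=axes)


# ---------------------------------------------------------------------------
# Step 1: bootstrap augmentation


def bootstrap_augment(C: SBSCatalogue, t: int, seed: int = 0) -> SBSCatalogue:
    """Resample each genome t times from Multinomial(N_g, p_g).

    Replicate IDs are the source ID suffixed with ``::b<i>``.  Genomes with
    zero mutations are carried through as zero rows (their multinomial is
    degenerate at zero).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    rng = np.random.default_rng(seed)
    totals = C.totals
    freqs = C.frequencies
    rows = np.zeros((C.n_samples * t, 96), dtype=np.int64)
    ids = []
    for g in range(C.n_samples):
        if totals[g] > 0:
            rows[g * t:(g + 1) * t] = rng.multinomial(totals[g], freqs[g], size=t)
        ids.extend(f"{C.sample_ids[g]}::b{i + 1}" for i in range(t))
    return SBSCatalogue(rows, ids)


# ---------------------------------------------------------------------------
# Step 2: multi-start training


def run_batch(
    C_aug: SBSCatalogue,
    C: SBSCatalogue,
    k: int,
    n: int,
    seeds: Sequence[int],
    xae_config: XAEConfig,
) -> list[RunWeights]:
    """Train n models on the augmented catalogue; score on the original.

    Each run uses its own seed; a run whose optimization diverges is
    retried once with a derived seed and recorded as failed if it diverges
    again.  More than 20% failed runs aborts the batch.
    """
    if n < 2:
        raise ValueError("need n >= 2 runs")
    if len(seeds) != n:
        raise ValueError(f"expected {n} seeds, got {len(seeds)}")
    runs: list[RunWeights] = []
    n_failed = 0
    for i, seed in enumerate(seeds):
        cfg = replace(xae_config, latent_dim=k, seed=int(seed))
        model = None
        for attempt_seed in (int(seed), _derive_seed(int(seed), 0x9E7)):
            try:
                model = PoissonMinVolumeAutoencoder(
                    replace(cfg, seed=attempt_seed)).fit(C_aug.counts)
                break
            except XAETrainingError:
                logger.warning("run %d for k=%d diverged (seed %d)",
                               i, k, attempt_seed)
                model = None
        if model is None:
            n_failed += 1
            runs.append(RunWeights(k, i, np.zeros((96, k)), np.zeros((96, k)),
                                   np.inf, int(seed), failed=True))
            continue
        W = model.W
        norms = np.linalg.norm(W, axis=0)
        W_norm = W / np.where(norms > 0, norms, 1.0)
        erec = reconstruction_error(model, C)
        runs.append(RunWeights(k, i, W, W_norm, erec, int(seed)))
    if n_failed > 0.2 * n:
        raise XAETrainingError(
            f"{n_failed}/{n} runs failed for k={k}; training is unstable"
        )
    return [r for r in runs if not r.failed] if n_failed else runs


# ---------------------------------------------------------------------------
# Step 3: K-means with matching


def _match_to_centroids(centroids: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Permutation assigning each centroid its best column of one run.

    Solves the k x k linear assignment problem minimizing total
    1 - cosine similarity; returns ``perm`` with ``perm[c]`` = column index
    assigned to centroid c.
    """
    sim = centroids.T @ cols  # columns are unit L2, so this is cosine
    row, col = linear_sum_assignment(1.0 - sim)
    perm = np.empty(centroids.shape[1], dtype=int)
    perm[row] = col
    return perm


def cluster_with_matching(runs: Sequence[RunWeights]) -> ConsensusSolution:
    """Group the runs' signature estimates into k equal-size clusters.

    Centroids start from the lowest-error run; each iteration matches every
    run's columns to the centroids one-to-one (linear assignment on
    1 - cosine) and recomputes the centroids as the normalized mean of
    their n assigned columns, until the assignment stabilizes (at most 100
    iterations).  The per-column silhouette is computed with cosine
    distance over all n*k columns; ``silhouette_min`` is the smallest
    per-cluster mean.  For k=1 (a single cluster) the silhouette is defined
    as one minus the mean intra-cluster cosine distance, which is 1 for
    identical runs and decreases with spread.
    """
    runs = [r for r in runs if not r.failed]
    if len(runs) < 2:
        raise ValueError("need at least 2 successful runs to form a consensus")
    k = runs[0].k
    if any(r.k != k for r in runs):
        raise ValueError("all runs must share the same k")
    n = len(runs)
    cols = [np.asarray(r.W_normalized, dtype=float) for r in runs]
    best_run = int(np.argmin([r.erec for r in runs]))
    centroids = cols[best_run].copy()
    # Guard against zero columns (dead signatures): give them unit norm.
    def _unitize(M: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(M, axis=0)
        return M / np.where(norms > 0, norms, 1.0)

    centroids = _unitize(centroids)
    assignment = np.zeros((n, k), dtype=int)
    for _ in range(100):
        new_assignment = np.vstack([
            _match_to_centroids(centroids, _unitize(c)) for c in cols
        ])
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        centroids = _unitize(np.stack(
            [np.mean([cols[i][:, assignment[i, c]] for i in range(n)], axis=0)
             for c in range(k)], axis=1))

    # Stack all n*k columns with their cluster labels for the silhouette;
    # assignment[i, c] = column of run i in cluster c, inverted to labels.
    all_cols = np.column_stack(cols).T  # (n*k, 96)
    labels = np.concatenate([_invert_perm(assignment[i]) for i in range(n)])
    if k == 1:
        dist = cosine_distances(all_cols)
        sil = np.full(n, 1.0) - dist.sum(axis=1) / (n - 1)
        sil_avg = float(sil.mean())
        sil_min = float(sil.mean())
    else:
        sil = silhouette_samples(cosine_distances(all_cols), labels,
                                 metric="precomputed")
        sil_avg = float(sil.mean())
        sil_min = float(min(sil[labels == c].mean() for c in range(k)))

    raw_centroids = np.stack(
        [np.mean([cols[i][:, assignment[i, c]] for i in range(n)], axis=0)
         for c in range(k)], axis=1)
    sums = raw_centroids.sum(axis=0)
    consensus = raw_centroids / np.where(sums > 0, sums, 1.0)
    signatures = SignatureMatrix(consensus, [f"DeNovo{j + 1}" for j in range(k)])
    membership = pd.DataFrame([
        {"run": runs[i].run_index, "column": int(assignment[i, c]), "cluster": c}
        for i in range(n) for c in range(k)
    ])
    erecs = [float(r.erec) for r in runs]
    return ConsensusSolution(
        k=k, signatures=signatures, silhouette_avg=sil_avg,
        silhouette_min=sil_min, mean_erec=float(np.mean(erecs)),
        run_erecs=erecs, membership=membership,
    )


def _invert_perm(perm: np.ndarray) -> np.ndarray:
    """Cluster label of each column given perm[cluster] = column."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv


# ---------------------------------------------------------------------------
# Steps 4-5: filtering and selection


def select_optimal(
    solutions: Sequence[ConsensusSolution],
    th_avg: float = 0.9,
    th_min: float = 0.7,
    config: ExtractionConfig | None = None,
) -> ExtractionResult:
    """Silhouette-filter the per-k solutions and pick the lowest-error k.

    Keeps solutions with ``silhouette_avg > th_avg`` and
    ``silhouette_min > th_min``; among them K* minimizes the mean
    reconstruction error, ties towards smaller k.  If nothing passes, the
    result is flagged unstable and K* falls back to the k with the highest
    average silhouette.
    """
    if not solutions:
        raise ValueError("no consensus solutions supplied")
    by_k = {s.k: s for s in solutions}
    passing = [s for s in solutions
               if s.silhouette_avg > th_avg and s.silhouette_min > th_min]
    if passing:
        best = min(passing, key=lambda s: (s.mean_erec, s.k))
        stable = True
    else:
        best = max(solutions, key=lambda s: (s.silhouette_avg, -s.k))
        stable = False
        logger.warning(
            "no k passed the silhouette filter (th_avg=%.2f th_min=%.2f); "
            "falling back to k=%d with the highest average silhouette",
            th_avg, th_min, best.k,
        )
    return ExtractionResult(
        selected_k=best.k, signatures=best.signatures, solutions=by_k,
        stable=stable, th_avg=th_avg, th_min=th_min, config=config,
    )


# ---------------------------------------------------------------------------
# Orchestration


def extract(C: SBSCatalogue, config: ExtractionConfig) -> ExtractionResult:
    """Run the full de novo extraction procedure on a catalogue."""
    boot_seed = _derive_seed(config.base_seed, 0xB007)
    C_aug = bootstrap_augment(C, config.t, seed=boot_seed)
    logger.info("augmented catalogue: %d samples (t=%d)", C_aug.n_samples, config.t)
    k_min, k_max = config.k_range
    solutions = []
    for k in range(k_min, k_max + 1):
        seeds = [_derive_seed(config.base_seed, k, i) for i in range(config.n)]
        runs = run_batch(C_aug, C, k, config.n, seeds, config.xae)
        sol = cluster_with_matching(runs)
        solutions.append(sol)
        logger.info(
            "k=%d: silhouette avg=%.4f min=%.4f mean_erec=%.2f",
            k, sol.silhouette_avg, sol.silhouette_min, sol.mean_erec,
        )
    return select_optimal(solutions, config.th_avg, config.th_min, config)


class DeNovoSignatureModel:
    """Model-object interface to de novo extraction.

    Parameters
    ----------
    catalogue : SBSCatalogue
        The observed SBS-96 counts.
    config : ExtractionConfig, optional
        Extraction settings; keyword overrides are applied on top.

    ``fit()`` runs the whole procedure and returns an
    :class:`ExtractionResult`.
    """

    def __init__(self, catalogue: SBSCatalogue,
                 config: ExtractionConfig | None = None, **overrides) -> None:
        self.catalogue = catalogue
        base = config if config is not None else ExtractionConfig()
        self.config = replace(base, **overrides) if overrides else base

    def fit(self, seed: int | None = None) -> ExtractionResult:
        cfg = self.config if seed is None else replace(self.config, base_seed=seed)
        return extract(self.catalogue, cfg)
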