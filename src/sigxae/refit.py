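"""Exposure assignment for a fixed signature set (refitting).

Given a catalogue and a set of signature profiles, the decoder of the
autoencoder is initialized with the column-normalized profiles and frozen;
only the encoder is trained, under the Poisson likelihood plus two L1
sparsity penalties — one on the weights of the final encoder layer and one
on the rectified latent output.  The non-negative latent z is the exposure
matrix: the number of mutations each signature
contributes to each genome.  The sparsity penalties discourage spreading a
genome's mutations over signatures that are not really active in it
(over-assignment).

Because the decoder is frozen, the minimum-volume penalty would be a
constant and is dropped exactly.  Since the frozen profiles are
column-stochastic, the reconstruction ``z @ S^T`` has the same row sums as
z, so the latent lives naturally on the mutation-count scale; an optional
final rescaling forces each sample's exposures to sum exactly to its
observed burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .autoencoder import PoissonMinVolumeAutoencoder, XAEConfig
from .catalogue import ExposureMatrix, SBSCatalogue, SignatureMatrix

__all__ = [
    "AssignmentConfig",
    "ExposureResult",
    "ExposureModel",
    "normalize_signatures",
    "assign_exposures",
]

logger = logging.getLogger(__name__)


@dataclass
class AssignmentConfig:
    """Settings for exposure refitting.

    ``l1_weights`` penalizes the final encoder layer's weights,
    ``l1_activity`` the rectified latent output; both push towards sparse
    exposures.  ``rescale_rows`` scales each sample's exposures to sum to
    its observed mutation burden.  Training stops early on the training
    loss (no validation split; the data being refit are the data of
    interest).
    """

    l1_weights: float = 1e-4
    l1_activity: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 50
    seed: int = 0
    rescale_rows: bool = False
    encoder_units: tuple[int, int, int] = (128, 64, 32)

    def __post_init__(self) -> None:
        if self.l1_weights < 0 or self.l1_activity < 0:
            raise ValueError("L1 penalties must be non-negative")

    def to_xae_config(self, k: int) -> XAEConfig:
        return XAEConfig(
            latent_dim=k,
            encoder_units=self.encoder_units,
            beta=0.0,  # constant once the decoder is frozen
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            validation_fraction=0.0,
            seed=self.seed,
            # A smooth rectifier instead of a hard ReLU: same non-negative
            # latent contract, but a sample can never fall into the
            # zero-gradient dead zone and stall the refit.
            latent_activation="softplus",
            l1_weights=self.l1_weights,
            l1_activity=self.l1_activity,
            freeze_decoder=True,
        )


def normalize_signatures(signatures: SignatureMatrix) -> SignatureMatrix:
    """Scale every signature column to sum to 1 (idempotent).

    Raises on all-zero columns, which cannot represent a mutational
    process.
    """
    return signatures.normalize()


def assign_exposures(
    catalogue: SBSCatalogue,
    signatures: SignatureMatrix,
    config: AssignmentConfig | None = None,
) -> ExposureMatrix:
    """Refit exposures of ``catalogue`` onto fixed ``signatures``.

    The signatures are normalized, loaded into the decoder and frozen;
    the encoder is trained to convergence; the rectified latent is
    returned (optionally rescaled to per-sample burdens).
    """
    return ExposureModel(catalogue, signatures, config).fit().exposures


@dataclass
class ExposureResult:
    """Fitted exposures plus the model and diagnostics behind them."""

    exposures: ExposureMatrix
    signatures: SignatureMatrix  # the normalized frozen profiles
    model: PoissonMinVolumeAutoencoder
    reconstruction_error: float
    config: AssignmentConfig

    def summary(self) -> str:
        Z = self.exposures.values
        active = (Z > 0.05 * max(Z.mean(), 1e-12)).mean()
        lines = [
            "Signature exposure refit",
            "=" * 24,
            f"samples: {Z.shape[0]}   signatures: {Z.shape[1]}",
            f"reconstruction error (Frobenius): {self.reconstruction_error:.2f}",
            f"mean exposures per signature:",
        ]
        for j, sid in enumerate(self.exposures.signature_ids):
            lines.append(f"  {sid:>12s}: {Z[:, j].mean():12.1f}")
        lines.append(f"fraction of non-negligible entries: {active:.2f}")
        return "\n".join(lines)

    def plot_exposures(self, ax=None, log: bool = True):
        """Heatmap of the fitted exposures."""
        from .plotting import plot_exposures
        return plot_exposures(self.exposures, ax=ax, log=log)


class ExposureModel:
    """Model object: catalogue + fixed signatures -> fitted exposures."""

    def __init__(
        self,
        catalogue: SBSCatalogue,
        signatures: SignatureMatrix,
        config: AssignmentConfig | None = None,
        **overrides,
    ) -> None:
        self.catalogue = catalogue
        self.signatures = normalize_signatures(signatures)
        base = config if config is not None else AssignmentConfig()
        self.config = replace(base, **overrides) if overrides else base

    def fit(self, seed: int | None = None) -> ExposureResult:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        k = self.signatures.k
        xae_cfg = cfg.to_xae_config(k)
        model = PoissonMinVolumeAutoencoder(
            xae_cfg, decoder_init=self.signatures.profiles
        )
        model.fit(self.catalogue.counts)
        Z = np.maximum(model.transform(self.catalogue), 0.0)
        if cfg.rescale_rows:
            sums = Z.sum(axis=1)
            totals = self.catalogue.totals.astype(float)
            zero = sums <= 0
            if zero.any():
                logger.warning(
                    "%d sample(s) received zero exposure everywhere; "
                    "left at zero despite rescale_rows", int(zero.sum()),
                )
            scale = np.where(zero, 0.0, totals / np.where(zero, 1.0, sums))
            Z = Z * scale[:, None]
        exposures = ExposureMatrix(
            Z, list(self.catalogue.sample_ids), list(self.signatures.signature_ids)
        )
        erec = float(np.linalg.norm(
            self.catalogue.counts - model.predict(self.catalogue), ord="fro"
        ))
        return ExposureResult(
            exposures=exposures, signatures=self.signatures, model=model,
            reconstruction_error=erec, config=cfg,
        )
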