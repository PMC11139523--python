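"""Synthetic SBS-96 cohort simulator with known ground truth.

Generates cohorts in which both the signature profiles and the per-sample
exposures are known exactly, for benchmarking de novo extraction.  The
generative model per sample is:

1. total burden ``N ~ round(LogNormal(mu, sigma))`` (at least 1);
2. each signature available to the sample's subcohort is switched on
   independently with its prevalence probability;
3. relative activities of the active signatures are drawn from a Dirichlet
   whose concentration is proportional to the subcohort's burden weights;
4. the burden is split over active signatures multinomially (these integer
   splits are the ground-truth exposures);
5. channel counts are the sum over active signatures of multinomial draws
   from each signature's 96-channel profile (or Poisson draws with the same
   means in ``poisson`` mode).

Five parametric cohort templates mimic the standard benchmark designs used
for signature-extraction tools: a single-cancer-type cohort (11 signatures),
a flat-signature two-subcohort mix (11), an overlapping-signature mix (11),
a three-signature two-subcohort mix, and a nine-cancer-type pan-cancer style
cohort (21 signatures).  Reference profiles (e.g. COSMIC) are not bundled;
by default well-separated random profiles stand in for them, and any 96 x k
signature TSV can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .catalogue import ExposureMatrix, SBSCatalogue, SignatureMatrix

__all__ = [
    "SubcohortSpec",
    "ScenarioSpec",
    "GroundTruth",
    "generate_signatures",
    "generate_cohort",
    "scenario_template",
    "SCENARIO_NAMES",
]

logger = logging.getLogger(__name__)


class SignatureSamplingError(RuntimeError):
    """Rejection sampling could not satisfy the similarity constraint."""


@dataclass
class SubcohortSpec:
    """One homogeneous group of samples within a scenario.

    ``signature_indices`` select columns of the supplied signature matrix;
    ``prevalences`` are per-signature Bernoulli activation probabilities and
    ``burden_weights`` set the Dirichlet concentration used to split each
    sample's burden across its active signatures.
    """

    name: str
    n_samples: int
    signature_indices: list[int]
    prevalences: list[float]
    burden_weights: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"subcohort {self.name!r}: n_samples must be >= 1")
        if len(self.prevalences) != len(self.signature_indices):
            raise ValueError(f"subcohort {self.name!r}: prevalence length mismatch")
        if any(not 0 <= p <= 1 for p in self.prevalences):
            raise ValueError(f"subcohort {self.name!r}: prevalences must be in [0,1]")
        if self.burden_weights is None:
            self.burden_weights = [1.0] * len(self.signature_indices)
        if len(self.burden_weights) != len(self.signature_indices):
            raise ValueError(f"subcohort {self.name!r}: burden_weights length mismatch")


@dataclass
class ScenarioSpec:
    """Parametric description of a synthetic cohort."""

    subcohorts: list[SubcohortSpec]
    burden_log_mean: float = float(np.log(3000.0))
    burden_log_sd: float = 1.0
    noise: str = "multinomial"  # or "poisson"
    dirichlet_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burden_log_sd < 0:
            raise ValueError("burden_log_sd must be >= 0")
        if self.noise not in ("multinomial", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.subcohorts)

    @property
    def signature_indices(self) -> list[int]:
        """Sorted union of signature indices used by any subcohort."""
        idx: set[int] = set()
        for s in self.subcohorts:
            idx.update(s.signature_indices)
        return sorted(idx)

    @property
    def k_true(self) -> int:
        return len(self.signature_indices)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        data = dict(data)
        data["subcohorts"] = [SubcohortSpec(**s) for s in data["subcohorts"]]
        return cls(**data)


@dataclass
class GroundTruth:
    """The planted truth behind a simulated cohort."""

    signatures: SignatureMatrix  # 96 x k_true, normalized, only planted columns
    exposures: ExposureMatrix  # m x k_true integer exposure counts
    labels: list[str]  # subcohort name per sample


def generate_signatures(
    k: int,
    max_pairwise_cosine: float = 0.6,
    sparsity: float = 0.5,
    seed: int = 0,
    concentration: float = 0.5,
    max_attempts: int = 20_000,
) -> SignatureMatrix:
    """Draw k well-separated random signature profiles.

    Each candidate profile is a Dirichlet draw over the 96 channels with a
    random fraction ``sparsity`` of channels zeroed out, mimicking the spiky
    support of real mutational processes.  Candidates are accepted by
    rejection sampling so that every pairwise cosine similarity stays at or
    below ``max_pairwise_cosine``.

    Raises
    ------
    SignatureSamplingError
        If the constraint cannot be met within ``max_attempts`` draws.
    """
    if not 1 <= k <= 96:
        raise ValueError("k must be between 1 and 96")
    if not 0 <= max_pairwise_cosine < 1:
        raise ValueError("max_pairwise_cosine must be in [0, 1)")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_zero = int(round(sparsity * 96))
    accepted: list[np.ndarray] = []
    for _ in range(max_attempts):
        profile = rng.dirichlet(np.full(96, concentration))
        if n_zero:
            profile = profile.copy()
            profile[rng.choice(96, size=n_zero, replace=False)] = 0.0
            total = profile.sum()
            if total <= 0:
                continue
            profile /= total
        unit = profile / np.linalg.norm(profile)
        if all(float(unit @ (q / np.linalg.norm(q))) <= max_pairwise_cosine
               for q in accepted):
            accepted.append(profile)
            if len(accepted) == k:
                profiles = np.column_stack(accepted)
                return SignatureMatrix(
                    profiles, [f"SIM{i + 1}" for i in range(k)]
                )
    raise SignatureSamplingError(
        f"could not draw {k} profiles with pairwise cosine <= "
        f"{max_pairwise_cosine} in {max_attempts} attempts"
    )


def _sample_exposure_row(
    rng: np.random.Generator,
    sub: SubcohortSpec,
    n_burden: int,
    concentration: float,
    k_slots: int,
    col_of: dict[int, int],
) -> np.ndarray:
    """Exposure counts for one sample over the scenario's k_true slots."""
    active = rng.random(len(sub.signature_indices)) < np.asarray(sub.prevalences)
    if not active.any():
        # No process switched on: fall back to the most prevalent one so the
        # sample still carries mutations.
        fallback = int(np.argmax(sub.prevalences))
        logger.debug(
            "sample in subcohort %s had no active signature; "
            "falling back to index %d", sub.name, sub.signature_indices[fallback],
        )
        active[fallback] = True
    idx = np.flatnonzero(active)
    weights = np.asarray(sub.burden_weights, dtype=float)[idx]
    alpha = concentration * weights
    activity = rng.dirichlet(alpha) if len(idx) > 1 else np.ones(1)
    split = rng.multinomial(n_burden, activity)
    row = np.zeros(k_slots, dtype=np.int64)
    for j, e in zip(idx, split):
        row[col_of[sub.signature_indices[j]]] = e
    return row


def generate_cohort(
    spec: ScenarioSpec, signatures: SignatureMatrix, seed: int | None = None
) -> tuple[SBSCatalogue, GroundTruth]:
    """Simulate a cohort under ``spec`` using the supplied signature profiles.

    Returns the observed catalogue and the exact planted ground truth
    (profiles restricted to the planted columns, integer exposures, and the
    subcohort label of every sample).  ``seed`` overrides ``spec.seed``.
    """
    sig_norm = signatures.normalize()
    used = spec.signature_indices
    if used and (min(used) < 0 or max(used) >= sig_norm.k):
        raise ValueError(
            f"scenario uses signature indices {used} but only "
            f"{sig_norm.k} signatures were supplied"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    col_of = {orig: j for j, orig in enumerate(used)}
    profiles = sig_norm.profiles[:, used]  # 96 x k_true

    counts_rows: list[np.ndarray] = []
    exposure_rows: list[np.ndarray] = []
    labels: list[str] = []
    sample_ids: list[str] = []
    for sub in spec.subcohorts:
        for i in range(sub.n_samples):
            n_burden = max(1, int(round(rng.lognormal(
                spec.burden_log_mean, spec.burden_log_sd))))
            exposure = _sample_exposure_row(
                rng, sub, n_burden, spec.dirichlet_concentration,
                len(used), col_of,
            )
            if spec.noise == "multinomial":
                channel = np.zeros(96, dtype=np.int64)
                for j in np.flatnonzero(exposure):
                    channel += rng.multinomial(exposure[j], profiles[:, j])
            else:
                lam = profiles @ exposure
                channel = rng.poisson(lam)
            counts_rows.append(channel)
            exposure_rows.append(exposure)
            labels.append(sub.name)
            sample_ids.append(f"{sub.name}::S{i + 1}")

    catalogue = SBSCatalogue(np.vstack(counts_rows), sample_ids)
    sig_ids = [sig_norm.signature_ids[j] for j in used]
    truth = GroundTruth(
        signatures=SignatureMatrix(profiles, sig_ids),
        exposures=ExposureMatrix(
            np.vstack(exposure_rows).astype(float), sample_ids, sig_ids
        ),
        labels=labels,
    )
    return catalogue, truth


# ---------------------------------------------------------------------------
# Scenario templates

SCENARIO_NAMES = ("scenario1", "scenario2", "scenario3", "scenario4", "scenario5")

# Recommended maximum pairwise cosine when the planted profiles are drawn by
# generate_signatures: the flat-signature and overlapping-signature designs
# deliberately contain similar profiles.
SCENARIO_SIGNATURE_SIMILARITY = {
    "scenario1": 0.6,
    "scenario2": 0.8,
    "scenario3": 0.8,
    "scenario4": 0.6,
    "scenario5": 0.6,
}


def _mix_prevalences(k: int, dominant: Sequence[int], high: float, low: float
                     ) -> list[float]:
    prev = [low] * k
    for j in dominant:
        prev[j] = high
    return prev


def scenario_template(name: str, scale: float = 1.0, seed: int = 0) -> ScenarioSpec:
    """Return the parametric spec of one of the five benchmark cohorts.

    ``scale`` multiplies every subcohort's sample count (rounded, minimum 1).
    The planted profiles themselves are supplied separately to
    :func:`generate_cohort` — generated by :func:`generate_signatures` or
    loaded from a reference signature file.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")

    def n(base: int) -> int:
        return max(1, int(round(base * scale)))

    if name == "scenario1":
        # One cohort; all 11 planted processes active in a broad fraction of
        # samples, moderate burdens.
        subs = [SubcohortSpec(
            "pancreas_like", n(1000), list(range(11)),
            prevalences=[0.7, 0.6, 0.5, 0.5, 0.4, 0.4, 0.35, 0.3, 0.3, 0.3, 0.3],
            burden_weights=[3, 2, 2, 1.5, 1.5, 1, 1, 1, 1, 1, 1],
        )]
        return ScenarioSpec(subs, burden_log_mean=float(np.log(3000)),
                            burden_log_sd=0.8, seed=seed)
    if name in ("scenario2", "scenario3"):
        # Two subcohorts sharing 11 signatures; each dominated by a small
        # set of (flat or overlapping) profiles.
        k = 11
        subs = [
            SubcohortSpec(
                "renal_like" if name == "scenario2" else "bladder_like",
                n(500), list(range(k)),
                prevalences=_mix_prevalences(k, (0, 1), 0.95, 0.15),
                burden_weights=_mix_prevalences(k, (0, 1), 5.0, 1.0),
            ),
            SubcohortSpec(
                "ovary_like" if name == "scenario2" else "skin_like",
                n(500), list(range(k)),
                prevalences=_mix_prevalences(k, (2, 3) if name == "scenario3"
                                             else (2,), 0.95, 0.15),
                burden_weights=_mix_prevalences(k, (2, 3) if name == "scenario3"
                                                else (2,), 5.0, 1.0),
            ),
        ]
        return ScenarioSpec(subs, burden_log_mean=float(np.log(3000)),
                            burden_log_sd=0.9, seed=seed)
    if name == "scenario4":
        # Only three planted processes in total across the two subcohorts.
        subs = [
            SubcohortSpec("renal_like", n(500), [0, 1, 2],
                          prevalences=[0.9, 0.9, 0.2],
                          burden_weights=[3.0, 3.0, 1.0]),
            SubcohortSpec("ovary_like", n(500), [0, 1, 2],
                          prevalences=[0.25, 0.25, 0.95],
                          burden_weights=[1.0, 1.0, 4.0]),
        ]
        return ScenarioSpec(subs, burden_log_mean=float(np.log(3000)),
                            burden_log_sd=0.7, seed=seed)
    if name == "scenario5":
        # Nine cancer-type subcohorts over 21 signatures: two ubiquitous
        # clock-like processes plus a rotating block of type-specific ones.
        k = 21
        subs = []
        type_names = ["bladder", "oesophagus", "breast", "lung_sq", "renal",
                      "ovary", "osteosarcoma", "cervix", "stomach"]
        for c, tname in enumerate(type_names):
            specific = [2 + (2 * c + d) % 19 for d in range(4)]
            prev = _mix_prevalences(k, specific, 0.8, 0.05)
            prev[0] = 0.9  # clock-like, everywhere
            prev[1] = 0.7
            w = _mix_prevalences(k, specific, 3.0, 1.0)
            w[0] = 2.0
            subs.append(SubcohortSpec(
                f"{tname}_like", n(300), list(range(k)), prev, w))
        return ScenarioSpec(subs, burden_log_mean=float(np.log(4000)),
                            burden_log_sd=0.9, seed=seed)
    raise ValueError(f"unknown scenario name {name!r}; choose from {SCENARIO_NAMES}")
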