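"""Piecewise-constant demographic models for forward simulation.

A demographic model is an ordered list of epochs (oldest first), each with a
diploid effective size and a duration in generations. A burn-in period at the
ancestral size precedes the first epoch so that allele-frequency distributions
reach (approximate) mutation-selection-drift stationarity before any size
change.

Models can be rescaled for desk-scale work: by diffusion invariance, dividing
sizes and durations by ``factor`` while multiplying ``s`` and ``mu`` by the
same factor leaves the site frequency spectrum (as a function of 2Ns)
unchanged up to discretization error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass(frozen=True)
class DemographicEpoch:
    """One constant-size epoch: ``duration`` generations at ``diploid_size``."""

    duration: int
    diploid_size: int

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError(f"epoch duration must be >= 1, got {self.duration}")
        if self.diploid_size < 2:
            raise ValueError(
                f"diploid size must be >= 2, got {self.diploid_size}"
            )


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs, oldest first, plus the stationarity burn-in length.

    ``burn_in_multiplier`` m prepends m * 2N_anc generations at the ancestral
    size before the first epoch.
    """

    epochs: tuple[DemographicEpoch, ...]
    burn_in_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("demographic model needs at least one epoch")
        if self.burn_in_multiplier < 1:
            raise ValueError("burn_in_multiplier must be >= 1")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @property
    def ancestral_size(self) -> int:
        return self.epochs[0].diploid_size

    @property
    def final_size(self) -> int:
        return self.epochs[-1].diploid_size

    def burn_in_generations(self) -> int:
        return int(round(self.burn_in_multiplier * 2 * self.ancestral_size))

    def size_trajectory(self) -> np.ndarray:
        """Diploid size for every generation, burn-in first, present last."""
        parts = [np.full(self.burn_in_generations(), self.ancestral_size)]
        for ep in self.epochs:
            parts.append(np.full(ep.duration, ep.diploid_size))
        return np.concatenate(parts).astype(np.int64)

    def rescaled(self, factor: float) -> "DemographicModel":
        """Shrink the model by ``factor`` (sizes and durations divided).

        The caller must multiply selection coefficients and the mutation rate
        by the same factor to preserve the diffusion limit.
        """
        if factor <= 0:
            raise ValueError("rescaling factor must be positive")
        eps = tuple(
            DemographicEpoch(
                duration=max(1, int(round(ep.duration / factor))),
                diploid_size=max(2, int(round(ep.diploid_size / factor))),
            )
            for ep in self.epochs
        )
        return DemographicModel(eps, self.burn_in_multiplier)

    def to_dict(self) -> dict:
        return {
            "epochs": [
                {"size": ep.diploid_size, "duration": ep.duration}
                for ep in self.epochs
            ],
            "burn_in_multiplier": float(self.burn_in_multiplier),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        eps = tuple(
            DemographicEpoch(duration=int(e["duration"]), diploid_size=int(e["size"]))
            for e in d["epochs"]
        )
        return cls(eps, float(d.get("burn_in_multiplier", 10.0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable short hash of the model, used to key SFS caches."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def toy_demography() -> DemographicModel:
    """Three-epoch desk-scale model: ancestral, bottleneck, growth.

    A shrunken caricature of a European-style history (out-of-Africa
    bottleneck followed by expansion). The ancestral size is chosen so that
    2N*s spans the drift barrier to strong selection across the package's
    default selection grid, and the growth epoch is large enough that
    strongly selected variants cannot reach the 1% common-variant threshold —
    the regime in which GWAS ascertainment reshapes hit architectures. The
    burn-in (5 x 2N ancestral generations, more than twice the neutral
    fixation timescale) brings allele frequencies to stationarity before the
    size changes.
    """
    return DemographicModel(
        epochs=(
            DemographicEpoch(duration=400, diploid_size=2048),
            DemographicEpoch(duration=100, diploid_size=512),
            DemographicEpoch(duration=200, diploid_size=16384),
        ),
        burn_in_multiplier=5.0,
    )


def constant_demography(diploid_size: int, duration: int = 1) -> DemographicModel:
    """Single-epoch constant-size model (neutral-SFS checks, oracles)."""
    return DemographicModel(
        epochs=(DemographicEpoch(duration=duration, diploid_size=diploid_size),)
    )
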