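"""Simulation configuration and ground-truth records.

A single :class:`SimConfig` drives every generator in :mod:`samgwas.synthgen`.
The master seed is expanded into independent per-generator substreams
(:meth:`SimConfig.rng`) so that, e.g., re-running only the genotype generator
reproduces exactly the genotypes of a full run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["SimConfig", "SyntheticTruth", "InvalidConfigError"]


class InvalidConfigError(ValueError):
    """A SimConfig field is outside its valid range."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real experiment's structure: a diverse inbred panel
    of 369 genotypes grown in 4 replicated batches, parabolic SAM profiles
    around 100 µm tall and 80 µm in radius, rare ALT alleles (common-allele
    frequency above 91%), and an entry-mean repeatability near 0.84 for the
    volume phenotype at 4 replicates.

    Attributes
    ----------
    seed:
        Master seed; fixed seed implies byte-identical generator output.
    n_genotypes, n_replicates:
        Panel size and biological replicates per genotype.
    pixel_scale:
        µm per pixel when rendering images (micrographs are ~1 µm/px here).
    noise_sd:
        SD (µm) of i.i.d. Gaussian noise added to contour points.
    height_median, radius_median, size_cv:
        Log-normal SAM size distribution across genotypes: medians (µm) and
        coefficient of variation. The panel's size distribution is not fully
        constrained by published summaries, so it is configurable.
    n_snps, n_subpops, fst:
        Genotype matrix dimensions and Balding–Nichols drift between
        subpopulations.
    alt_freq_range:
        Ancestral ALT-allele frequency range; (0.01, 0.09) keeps realized
        common-allele frequencies above 0.91 at almost all sites.
    missing_rate:
        Per-call missingness of the genotype matrix.
    causal_effects:
        List of (snp_index, effect) pairs; effect is the phenotype shift in
        µm³ per ALT allele copy (genotypes are coded 0/2).
    h2_polygenic:
        Replicate-level polygenic heritability σ²_g/(σ²_g+σ²_e); the default
        0.5676 yields entry-mean repeatability 0.84 at 4 replicates.
    pheno_mean, pheno_sd:
        Grand mean and total (genetic+residual) SD of the phenotype (µm³);
        defaults are in the range of maize SAM volumes.
    batch_effect_sd:
        SD (µm³) of additive replicate-level batch shifts.
    germination_dropout:
        Fraction of genotype×replicate cells dropped (failed germination).
    """

    seed: int = 0
    n_genotypes: int = 369
    n_replicates: int = 4
    pixel_scale: float = 1.0
    noise_sd: float = 2.0
    height_median: float = 100.0
    radius_median: float = 80.0
    size_cv: float = 0.15
    n_snps: int = 5000
    n_subpops: int = 3
    fst: float = 0.1
    alt_freq_range: tuple[float, float] = (0.01, 0.09)
    missing_rate: float = 0.1
    causal_effects: list[tuple[int, float]] = field(default_factory=list)
    h2_polygenic: float = 0.5676
    pheno_mean: float = 1.0e6
    pheno_sd: float = 2.0e5
    batch_effect_sd: float = 2.0e4
    germination_dropout: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genotypes <= 0 or self.n_replicates <= 0 or self.n_snps <= 0:
            raise InvalidConfigError("counts must be positive")
        if self.n_subpops <= 0:
            raise InvalidConfigError("n_subpops must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        lo, hi = self.alt_freq_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("alt_freq_range must lie in (0, 0.5]")
        for name in ("missing_rate", "fst", "germination_dropout"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if not (0 <= self.h2_polygenic < 1):
            raise InvalidConfigError("h2_polygenic must be in [0, 1)")
        if self.pixel_scale <= 0:
            raise InvalidConfigError("pixel_scale must be positive")
        for idx, _ in self.causal_effects:
            if not (0 <= idx < self.n_snps):
                raise InvalidConfigError(f"causal SNP index {idx} out of range")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator, derived from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_stream_key(stream),))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["alt_freq_range"] = list(self.alt_freq_range)
        d["causal_effects"] = [list(t) for t in self.causal_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "alt_freq_range" in d:
            d["alt_freq_range"] = tuple(d["alt_freq_range"])
        if "causal_effects" in d:
            d["causal_effects"] = [tuple(t) for t in d["causal_effects"]]
        return cls(**d)


def _stream_key(stream: str) -> int:
    # stable small integer per stream name (independent of PYTHONHASHSEED)
    return int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little") % (2**31)


@dataclass
class SyntheticTruth:
    """Ground truth written by the generators, consumed only by tests.

    Generators record what they drew (true per-genotype SAM height/radius,
    causal SNP ids and effects, variance components, nuclei counts); the
    analysis pipeline never reads these fields.
    """

    true_h: dict[str, float] = field(default_factory=dict)
    true_r: dict[str, float] = field(default_factory=dict)
    replicate_h: dict[tuple[str, str], float] = field(default_factory=dict)
    replicate_r: dict[tuple[str, str], float] = field(default_factory=dict)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    batch_effects: dict[str, float] = field(default_factory=dict)
    genetic_values: dict[str, float] = field(default_factory=dict)
    nuclei: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _keyed(d: dict) -> dict:
            return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in d.items()}

        payload = {
            "true_h": self.true_h,
            "true_r": self.true_r,
            "replicate_h": _keyed(self.replicate_h),
            "replicate_r": _keyed(self.replicate_r),
            "causal_snps": [list(t) for t in self.causal_snps],
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "batch_effects": self.batch_effects,
            "genetic_values": self.genetic_values,
            "nuclei": self.nuclei,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
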