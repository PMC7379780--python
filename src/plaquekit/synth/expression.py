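"""Synthetic expression matrices with planted co-expression modules.

Emulates the statistical structure the module-trait workflow assumes: a
genes × samples matrix of normalized log-scale values in which each
planted module is driven by a latent factor tracking one binary trait
(APOE isoform, Trem2 status, APP transgene or sex), module genes carry a
shared batch shift, background genes are pure noise, and per-sample
amyloid coverage (for APP-transgenic samples) is coupled to one module's
latent factor within every APP group except a designated uncoupled one.

With gene ``x_g = loading_g · s · L + batch + noise`` (effect size ``s``,
unit-variance latent ``L``, unit loadings, noise SD 1) the expected
within-module correlation is ``s²/(s²+1)`` — 0.8 at the default ``s=2``.

The default design reproduces the study's eight genotype groups and
sample sizes (total n = 88).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModuleSpec", "ExprSpec", "generate_expression", "DEFAULT_GROUP_SIZES"]

# genotype -> n samples; (APOE, Trem2, APP)
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "E3": 8,
    "E3/Trem2ko": 8,
    "E4": 6,
    "E4/Trem2ko": 8,
    "APP/E3": 14,
    "APP/E3/Trem2ko": 14,
    "APP/E4": 14,
    "APP/E4/Trem2ko": 16,
}

TRAIT_COLUMNS = ("APOE", "Trem2", "APP", "sex")


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int = 60
    trait: str = "Trem2"  # which binary trait the latent factor tracks
    effect_size: float = 2.0  # SD of the latent signal relative to unit noise
    loading_sd: float = 0.3  # gene loadings ~ N(1, loading_sd)
    latent_trait_r: float = 0.7  # correlation of the latent with the coded trait
    # hub genes: the first n_hub_genes of the module carry a fixed high
    # loading (the strongly connected genes a hub search should find);
    # non-hub loadings are clipped below the hub level
    n_hub_genes: int = 5
    hub_loading: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 <= self.n_hub_genes <= self.size:
            raise ValueError("n_hub_genes must lie in [0, size]")
        if self.trait not in TRAIT_COLUMNS:
            raise ValueError(f"trait must be one of {TRAIT_COLUMNS}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if not -1 <= self.latent_trait_r <= 1:
            raise ValueError("latent_trait_r must lie in [-1, 1]")


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(trait="Trem2"),
        ModuleSpec(trait="APOE"),
        ModuleSpec(trait="APP"),
    ]


@dataclass
class ExprSpec:
    """Parameters of one synthetic expression study."""

    n_genes: int = 2000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    modules: list[ModuleSpec] = field(default_factory=_default_modules)
    noise_sd: float = 1.0
    batch_effect: float = 1.0  # shared shift on module genes per batch contrast
    coverage_r: float = 0.8  # within-group coupling of coverage to the first module
    coverage_module: int = 0
    coverage_uncoupled_group: str = "APP/E3/Trem2ko"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes sum to more than n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1 <= self.coverage_r <= 1:
            raise ValueError("coverage_r must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


def _design_table(spec: ExprSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in spec.group_sizes.items():
        for i in range(n):
            rows.append(
                {
                    "group": group,
                    "APOE": "E4" if "E4" in group else "E3",
                    "Trem2": "ko" if "Trem2ko" in group else "wt",
                    "APP": "tg" if group.startswith("APP") else "wt",
                    "sex": "F" if i % 2 == 0 else "M",
                }
            )
    design = pd.DataFrame(rows)
    design.index = [f"S{i+1:03d}" for i in range(len(design))]
    # sequencing batch: random balanced split, independent of genotype
    half = len(design) // 2
    batch = np.array(["b1"] * half + ["b2"] * (len(design) - half))
    design["batch"] = rng.permutation(batch)
    return design


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_expression(
    spec: ExprSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate ``(expression, design, truth)``.

    ``expression`` is genes × samples; ``design`` holds the genotype
    annotations, sex and batch plus the numeric trait codes and, for
    APP-transgenic samples, the per-sample amyloid ``coverage`` values.
    ``truth`` records gene → module membership, the latent factors, the
    empirical latent–trait correlations and any degeneracy warnings.
    Identical spec (incl. seed) gives an identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    design = _design_table(spec, rng)
    n = len(design)
    warnings: list[str] = []

    trait_codes = pd.DataFrame(index=design.index)
    trait_codes["APOE"] = (design["APOE"] == "E4").astype(float)
    trait_codes["Trem2"] = (design["Trem2"] == "ko").astype(float)
    trait_codes["APP"] = (design["APP"] == "tg").astype(float)
    trait_codes["sex"] = (design["sex"] == "M").astype(float)
    for col in trait_codes:
        if trait_codes[col].nunique() < 2:
            warnings.append(f"trait {col!r} is constant across samples")

    batch_z = _standardize((design["batch"] == "b2").to_numpy(float))

    gene_ids = [f"G{i+1:05d}" for i in range(spec.n_genes)]
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    membership = np.array(["unassigned"] * spec.n_genes, dtype=object)
    latents = {}
    latent_trait_corr = {}
    hub_lists: dict[str, list[str]] = {}
    loading_map: dict[str, float] = {}
    start = 0
    for k, mod in enumerate(spec.modules):
        name = f"M{k+1}"
        t_z = _standardize(trait_codes[mod.trait].to_numpy())
        eps = rng.standard_normal(n)
        latent = mod.latent_trait_r * t_z + np.sqrt(1 - mod.latent_trait_r**2) * eps
        latent = _standardize(latent)
        loadings = rng.normal(1.0, mod.loading_sd, size=mod.size)
        if mod.n_hub_genes:
            # keep non-hub loadings strictly below the hub level so the
            # planted hubs are the unambiguous top of the module
            np.clip(loadings, 0.4, 0.6 * mod.hub_loading, out=loadings)
            loadings[: mod.n_hub_genes] = mod.hub_loading
        rows = slice(start, start + mod.size)
        X[rows, :] += (
            np.outer(loadings, mod.effect_size * latent)
            + spec.batch_effect * batch_z[None, :]
        )
        membership[rows] = name
        hub_lists[name] = gene_ids[start : start + mod.n_hub_genes]
        loading_map.update(dict(zip(gene_ids[start : start + mod.size], loadings)))
        latents[name] = latent
        if t_z.std() > 0:
            latent_trait_corr[name] = float(np.corrcoef(latent, t_z)[0, 1])
        else:
            latent_trait_corr[name] = np.nan
        start += mod.size

    expr = pd.DataFrame(X, index=gene_ids, columns=design.index)
    design = design.join(trait_codes.add_suffix("_code"))

    # per-sample amyloid coverage for APP samples, coupled within-group to
    # the chosen module's latent except in the designated uncoupled group
    coverage = pd.Series(np.nan, index=design.index, name="coverage")
    if spec.modules:
        lat = pd.Series(latents[f"M{spec.coverage_module + 1}"], index=design.index)
        for group in [g for g in spec.group_sizes if g.startswith("APP")]:
            idx = design.index[design["group"] == group]
            lz = _standardize(lat[idx].to_numpy())
            eps = rng.standard_normal(len(idx))
            r = 0.0 if group == spec.coverage_uncoupled_group else spec.coverage_r
            z = r * lz + np.sqrt(1 - r**2) * eps
            coverage[idx] = np.clip(8.0 + 3.0 * z, 0.2, None)
    design["coverage"] = coverage

    truth = {
        "membership": pd.Series(membership, index=gene_ids, name="module"),
        "latents": pd.DataFrame(latents, index=design.index),
        "latent_trait_r": latent_trait_corr,
        "hubs": hub_lists,
        "loadings": pd.Series(loading_map, name="loading"),
        "warnings": warnings,
    }
    return expr, design, truth
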