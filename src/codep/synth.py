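"""Synthetic dependency screens with planted co-essential modules.

Each module is a block of genes sharing one latent per-cell factor
(single-factor compound symmetry): gene g in module m takes

    x_gc = s_g * sqrt(rho) * f_mc + sqrt(1 - rho) * eps_gc

with f_mc and eps_gc independent standard normal and s_g = +/-1 the
gene's membership sign, so two members correlate at s_g * s_h * rho.
Negative-sign members emulate pathway inhibitors whose dependencies
anti-correlate with the drivers'.  A module may be restricted to one
tumour lineage: cells outside it receive pure unit-variance noise, so
the module is only detectable after filtering to that lineage.  Noise
genes are fully independent, and entries are masked missing uniformly
at random.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from codep.io import GeneSet, GeneSetCollection

TRUTH_COLUMNS = ["gene", "module", "sign", "lineage"]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-dependency module.

    size
        Number of member genes.
    rho
        Target within-module correlation magnitude, in [0, 1).
    neg_frac
        Fraction of members with negative sign (anti-correlated with the
        positive members); the count is rounded to the nearest integer.
    lineage
        If set, the module's latent factor drives only the cells of this
        lineage; elsewhere the member genes are plain noise.
    """

    size: int
    rho: float
    neg_frac: float = 0.0
    lineage: str | None = None

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.neg_frac <= 1.0:
            raise ValueError("neg_frac must lie in [0, 1]")

    @property
    def n_negative(self) -> int:
        return int(round(self.neg_frac * self.size))


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic screen."""

    n_cells: int
    modules: tuple = ()
    n_noise: int = 0
    missing_rate: float = 0.0
    lineages: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        object.__setattr__(self, "modules", tuple(self.modules))
        if self.lineages is not None:
            total = sum(self.lineages.values())
            if total != self.n_cells:
                raise ValueError(
                    f"lineage cell counts sum to {total}, expected "
                    f"{self.n_cells}"
                )
        for mod in self.modules:
            if mod.lineage is not None and (
                self.lineages is None or mod.lineage not in self.lineages
            ):
                raise ValueError(
                    f"module lineage {mod.lineage!r} not in the lineage map"
                )


def _lineage_assignment(config: SynthConfig) -> list:
    if config.lineages is None:
        return ["pan"] * config.n_cells
    out = []
    for lin, count in config.lineages.items():
        out.extend([lin] * count)
    return out


def simulate(config: SynthConfig):
    """Draw one synthetic screen.

    Returns ``(matrix, metadata, truth)``: a samples x genes dependency
    matrix with NaN for masked entries, a metadata table (sample id,
    display name, lineage plus three empty subtype slots), and the truth
    table mapping every gene to its module (or ``"noise"``), sign and
    lineage restriction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    cell_lineages = _lineage_assignment(config)

    gene_ids: list[str] = []
    truth_rows: list[tuple] = []
    blocks: list[np.ndarray] = []

    for m_idx, mod in enumerate(config.modules, start=1):
        mod_id = f"M{m_idx}"
        factor = rng.standard_normal(n)
        signs = np.ones(mod.size, dtype=int)
        if mod.n_negative:
            signs[mod.size - mod.n_negative:] = -1
        eps = rng.standard_normal((n, mod.size))
        loading = np.sqrt(mod.rho)
        resid = np.sqrt(1.0 - mod.rho)
        block = signs[None, :] * loading * factor[:, None] + resid * eps
        if mod.lineage is not None:
            outside = np.array([l != mod.lineage for l in cell_lineages])
            block[outside] = rng.standard_normal((int(outside.sum()), mod.size))
        blocks.append(block)
        width = max(3, len(str(mod.size)))
        for g_idx in range(mod.size):
            gene = f"{mod_id}G{g_idx + 1:0{width}d}"
            gene_ids.append(gene)
            truth_rows.append(
                (gene, mod_id, int(signs[g_idx]), mod.lineage or "")
            )

    if config.n_noise:
        blocks.append(rng.standard_normal((n, config.n_noise)))
        width = max(4, len(str(config.n_noise)))
        for g_idx in range(config.n_noise):
            gene = f"NG{g_idx + 1:0{width}d}"
            gene_ids.append(gene)
            truth_rows.append((gene, "noise", 1, ""))

    values = np.concatenate(blocks, axis=1) if blocks else np.empty((n, 0))
    if config.missing_rate > 0.0 and values.size:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan

    sample_ids = [f"CL{i + 1:04d}" for i in range(n)]
    matrix = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                          columns=pd.Index(gene_ids, name="gene"))
    metadata = pd.DataFrame(
        {
            "display_name": [f"cellline-{i + 1}" for i in range(n)],
            "lineage": cell_lineages,
            "lineage_subtype_1": "",
            "lineage_subtype_2": "",
            "lineage_subtype_3": "",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return matrix, metadata, truth


def make_pathway_sets(truth: pd.DataFrame) -> GeneSetCollection:
    """One gene set per planted module (noise genes belong to no set)."""
    sets = []
    for mod_id, group in truth[truth["module"] != "noise"].groupby(
        "module", sort=True
    ):
        sets.append(
            GeneSet(
                set_id=str(mod_id),
                description=f"planted module {mod_id}",
                members=frozenset(group["gene"]),
            )
        )
    return GeneSetCollection(sets)
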