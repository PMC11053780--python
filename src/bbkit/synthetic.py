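"""Seeded generators for every input the analysis modules consume.

The generators state a small world with known ground truth:

* binding panels — one base profile of negative per-residue energies plus
  iid Gaussian ligand-specific perturbations, so RMSD_BM against the base
  recovers the noise sd (chi-distributed under divisor n);
* contact tables — built from target enrichment ratios and surface
  proportions by a fixed-point iteration, so deriving the composition and
  enrichment from the generated table returns the targets to float
  tolerance;
* NQR sites — (cqcc, η) sampled inside the experimentally typical envelope
  and emitted through the exact forward map, so parameter recovery is an
  identity;
* frontier-orbital pairs — HOMO/LUMO sampled from disjoint envelopes so
  every pair is physically ordered.

Everything is driven by one integer seed; the same seed reproduces the
same objects bit for bit.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .binding import BindingModePanel, BindingModeVector
from .contacts import ContactTable, SurfaceComposition, pair_order
from .errors import ConfigError
from .nqr import NQRTriplet, QuadrupoleParams, frequencies_from_quadrupole
from .reactivity import FrontierEnergies

__all__ = [
    "GeneratorConfig",
    "gen_binding_panel",
    "gen_contact_table",
    "gen_nqr_sites",
    "gen_frontier_energies",
]

# Ara-C-like surface, rounded so the proportions sum to exactly 100.
DEFAULT_SURFACE = {"C": 7.0, "H": 67.5, "N": 7.0, "O": 18.5}


class GeneratorConfig(BaseModel):
    """Shared knobs for all generators.

    ``noise_sd`` is the per-residue Gaussian sd in the panel's energy units
    (kcal/mol); ``cqcc_range``/``eta_range`` bound the sampled quadrupole
    parameters (MHz, dimensionless); ``homo_range``/``lumo_range`` are eV.
    """

    seed: int = 0
    n_ligands: int = 12
    n_residues: int = 18
    n_sites: int = 10
    noise_sd: float = 1.0
    clip_nonpositive: bool = False
    surface_proportions: dict[str, float] = DEFAULT_SURFACE
    enrichment_targets: Optional[dict[str, float]] = None
    cqcc_range: tuple[float, float] = (2.0, 4.0)
    eta_range: tuple[float, float] = (0.0, 0.95)
    homo_range: tuple[float, float] = (-8.5, -7.0)
    lumo_range: tuple[float, float] = (-0.8, 0.3)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_ligands < 1 or self.n_residues < 1 or self.n_sites < 1:
            raise ConfigError("counts must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        total = sum(self.surface_proportions.values())
        if abs(total - 100.0) > 1e-6:
            raise ConfigError(f"surface proportions must sum to 100, got {total}")
        for lo, hi in (self.cqcc_range, self.eta_range, self.homo_range, self.lumo_range):
            if hi < lo:
                raise ConfigError(f"empty range ({lo}, {hi})")
        if self.homo_range[1] >= self.lumo_range[0]:
            raise ConfigError("HOMO envelope must lie strictly below the LUMO envelope")
        return self


def _rng(cfg: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def gen_binding_panel(
    cfg: GeneratorConfig,
) -> tuple[BindingModePanel, dict]:
    """Base profile + iid Gaussian perturbation per ligand.

    The base emulates a docking panel's dynamic range: energies decay from
    about −25 kcal/mol at the strongest residue down to −0.3.  Ground truth
    records the base vector and each ligand's noise sd.
    """
    import warnings

    rng = _rng(cfg)
    # strongest-first profile on a docking-panel-like scale
    base = -np.sort(rng.uniform(0.3, 25.0, size=cfg.n_residues))[::-1]
    residues = [f"RES{i + 1:03d}" for i in range(cfg.n_residues)]
    truth: dict = {"base": base.tolist(), "noise_sd": {}}
    with warnings.catch_warnings():
        # unclipped noise legitimately crosses zero near weak residues;
        # the sign-convention warning is for ingested data, not for this
        warnings.simplefilter("ignore", UserWarning)
        ligands = [BindingModeVector(ligand_id="base", entries=dict(zip(residues, base)))]
        for j in range(cfg.n_ligands):
            noisy = base + rng.normal(0.0, cfg.noise_sd, size=cfg.n_residues)
            if cfg.clip_nonpositive:
                noisy = np.minimum(noisy, 0.0)
            lig = f"L{j + 1:02d}"
            ligands.append(
                BindingModeVector(ligand_id=lig, entries=dict(zip(residues, noisy)))
            )
            truth["noise_sd"][lig] = cfg.noise_sd
        panel = BindingModePanel(
            residues=residues,
            ligands=ligands,
            metadata={"generator": "gen_binding_panel"},
        )
    return panel, truth


def gen_contact_table(cfg: GeneratorConfig) -> tuple[ContactTable, dict]:
    """Contact table whose derived enrichment equals a stated target map.

    Solves the self-consistency C_XY = E_XY * R_XY(S), S = S(C) by damped
    fixed-point iteration starting from the configured proportions.  A
    total-100 table constrains the random-weighted mean of E to exactly 1,
    so an arbitrary requested map is feasible only up to one uniform scale;
    the ground truth records both the request and the achieved map
    (``targets``), which the table reproduces to float tolerance.  With all
    targets 1 no rescaling occurs ((ΣS)²/100 = 100).
    """
    species = tuple(cfg.surface_proportions)
    order = pair_order(species)
    targets = {p: 1.0 for p in order}
    if cfg.enrichment_targets:
        for k, v in cfg.enrichment_targets.items():
            if k not in targets:
                raise ConfigError(f"unknown pair {k!r} for species {species}")
            if v < 0:
                raise ConfigError(f"negative enrichment target for {k}: {v}")
            targets[k] = v

    s = np.array([cfg.surface_proportions[x] for x in species], dtype=float)
    idx = {x: i for i, x in enumerate(species)}

    def table_from(s_vec: np.ndarray) -> dict[str, float]:
        c = {}
        for p in order:
            x, y = p[0], p[1]
            if x == y:
                r = s_vec[idx[x]] ** 2 / 100.0
            else:
                r = 2.0 * s_vec[idx[x]] * s_vec[idx[y]] / 100.0
            c[p] = targets[p] * r
        return c

    for _ in range(5000):  # linear convergence; typical maps need ~10^3 steps
        c = table_from(s)
        derived = np.array(
            [
                c[x + x] + 0.5 * sum(c[p] for p in order if x in p and p != x + x)
                for x in species
            ]
        )
        total = derived.sum()
        if total <= 0:
            raise ConfigError("enrichment targets drive the surface to zero")
        new_s = derived * 100.0 / total
        if np.max(np.abs(new_s - s)) < 1e-12:
            s = new_s
            break
        s = 0.5 * s + 0.5 * new_s
    else:
        raise ConfigError("enrichment self-consistency iteration did not converge")

    c = table_from(s)
    total = sum(c.values())
    c = {p: v * 100.0 / total for p, v in c.items()}
    if any(v < 0 for v in c.values()):
        raise ConfigError("infeasible enrichment targets (negative contribution)")
    table = ContactTable(
        structure_id=f"synthetic-{cfg.seed}", contributions=c, species=species
    )
    truth = {
        # achieved map: request times the feasibility scale 100/total
        "targets": {p: v * 100.0 / total for p, v in targets.items()},
        "requested_targets": dict(targets),
        "surface": SurfaceComposition(
            proportions=dict(zip(species, s.tolist())),
            structure_id=table.structure_id,
        ),
    }
    return table, truth


def gen_nqr_sites(
    cfg: GeneratorConfig,
) -> tuple[list[NQRTriplet], list[QuadrupoleParams]]:
    """Sample (cqcc, η) uniformly in the envelope; emit exact triplets."""
    rng = _rng(cfg)
    triplets, params = [], []
    for i in range(cfg.n_sites):
        p = QuadrupoleParams(
            cqcc=float(rng.uniform(*cfg.cqcc_range)),
            eta=float(rng.uniform(*cfg.eta_range)),
            site_label=f"site{i + 1:02d}",
        )
        params.append(p)
        triplets.append(frequencies_from_quadrupole(p))
    return triplets, params


def gen_frontier_energies(
    cfg: GeneratorConfig,
) -> tuple[list[FrontierEnergies], str]:
    """Physically ordered HOMO/LUMO pairs; the first ligand is the
    designated reference for relative-reactivity tests."""
    rng = _rng(cfg)
    out = []
    for j in range(cfg.n_ligands):
        out.append(
            FrontierEnergies(
                ligand_id=f"L{j + 1:02d}",
                e_homo=float(rng.uniform(*cfg.homo_range)),
                e_lumo=float(rng.uniform(*cfg.lumo_range)),
            )
        )
    return out, out[0].ligand_id
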