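"""Seeded synthetic fixtures: molecules, electronic states and calibration data.

These generators emulate the statistical shape of the study inputs —
chain-like or lightly branched heavy-atom skeletons, per-atom SET values
near 1, a single optional oxygen with a dipolar context, and noisy linear
descriptor -> log P relationships — without any quantum-chemical realism.
Every draw is driven by an explicit seed through a private
``numpy.random.Generator``; identical specs reproduce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .descriptor import AtomElectronicState, DipolarContext
from .molgraph import MoleculeGraph

__all__ = ["SynthSpec", "synth_molecule", "synth_calibration_dataset"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic molecule.

    ``set_distribution`` is (mean, spread) of a normal draw for per-atom
    SET values, truncated away from zero; the default (0.95, 0.05) mirrors
    the near-unity SET values of saturated carbons.  ``mu_range`` bounds a
    uniform dipole-moment draw (Debye) used only when a heteroatom is
    present.
    """

    n_atoms: int
    topology: Literal["chain", "branched"] = "chain"
    heteroatom_position: int | None = None
    set_distribution: tuple[float, float] = (0.95, 0.05)
    mu_range: tuple[float, float] = (1.5, 3.5)
    seed: int = 0


def _chain_bonds(n: int) -> set[frozenset[int]]:
    return {frozenset((i, i + 1)) for i in range(1, n)}


def _branched_bonds(n: int, rng: np.random.Generator) -> set[frozenset[int]]:
    # random labelled tree: attach atom k to a uniformly chosen earlier atom,
    # capping heavy degree at 4
    bonds: set[frozenset[int]] = set()
    degree = {i: 0 for i in range(1, n + 1)}
    for k in range(2, n + 1):
        candidates = [i for i in range(1, k) if degree[i] < 4]
        parent = int(rng.choice(candidates))
        bonds.add(frozenset((parent, k)))
        degree[parent] += 1
        degree[k] += 1
    return bonds


def synth_molecule(
    spec: SynthSpec,
) -> tuple[MoleculeGraph, list[AtomElectronicState], DipolarContext | None]:
    """Draw one synthetic molecule with per-atom SET values.

    The heteroatom (an oxygen standing in for any polar site), when
    requested, gets a negative net charge and a dipolar context against
    one of its carbon neighbours; without it the molecule is apolar and
    the context is ``None``.
    """
    if spec.n_atoms < 1:
        raise ValueError(f"need at least one atom, got {spec.n_atoms}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    if spec.topology == "chain":
        bonds = _chain_bonds(n)
    elif spec.topology == "branched":
        bonds = _branched_bonds(n, rng)
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")

    het = spec.heteroatom_position
    if het is not None and not (1 <= het <= n):
        raise ValueError(f"heteroatom position {het} outside 1..{n}")
    if het is not None and n == 1:
        raise ValueError("a lone heteroatom has no carbon partner for the dipole")
    elements = tuple("O" if i == het else "C" for i in range(1, n + 1))
    g = MoleculeGraph(elements=elements, bonds=frozenset(bonds))

    mean, spread = spec.set_distribution
    sets = rng.normal(mean, spread, size=n)
    sets = np.clip(sets, 0.05, None)  # SET values must stay positive
    charges = rng.normal(-0.05, 0.05, size=n)
    states = [
        AtomElectronicState(
            index=i, element=g.element(i),
            net_charge=float(charges[i - 1]),
            set_value=float(sets[i - 1]),
        )
        for i in g.atom_indices
    ]

    ctx = None
    if het is not None:
        c_idx = min(g.neighbors(het))
        mu = float(rng.uniform(*spec.mu_range))
        q_x = float(-abs(rng.normal(0.28, 0.03)))
        q_c = float(abs(rng.normal(0.22, 0.03)))
        states = [
            replace(s, net_charge=q_x) if s.index == het
            else (replace(s, net_charge=q_c) if s.index == c_idx else s)
            for s in states
        ]
        ctx = DipolarContext(
            mu=mu, d=float(rng.uniform(1.2, 1.45)),
            q_c=q_c, q_x=q_x, c_index=c_idx, x_index=het,
        )
    return g, states, ctx


def synth_calibration_dataset(
    a: float, b: float, sigma: float, n: int, seed: int,
    x_range: tuple[float, float] = (2.0, 18.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy linear descriptor -> log P data: y = a + b x + N(0, sigma).

    ``x`` is drawn uniformly over ``x_range`` (the default spans the
    descriptor range of the study compounds).
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if sigma < 0:
        raise ValueError(f"noise level must be nonnegative, got {sigma}")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    y = a + b * x + rng.normal(0.0, sigma, size=n) if sigma > 0 else a + b * x
    return x, np.asarray(y, dtype=float)


def sidecar_from_states(
    states: list[AtomElectronicState],
    ctx: DipolarContext | None,
    name: str = "synthetic",
) -> dict:
    """Assemble the electronic-state sidecar mapping for a synthetic draw."""
    sidecar: dict = {
        "name": name,
        "dipole_debye": 0.0 if ctx is None else ctx.mu,
        "atoms": [
            {
                "index": s.index,
                "element": s.element,
                "net_charge_e": s.net_charge,
                "set_value": s.set_value,
            }
            for s in states
        ],
    }
    if ctx is not None:
        sidecar["polar_group"] = {
            "c_index": ctx.c_index,
            "x_index": ctx.x_index,
            "bond_length_angstrom": ctx.d,
        }
    return sidecar
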