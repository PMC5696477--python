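"""Equilibrium Boltzmann populations of a conformer ensemble.

The population of conformer *i* at temperature *T* is

    p_i(T) = 100 * exp(-G_i/(kB*T)) / sum_j exp(-G_j/(kB*T))   [percent]

with G_i = e_rel_i + g_corr_i(T) re-referenced so that min_i G_i = 0.
Free-energy corrections at unlisted temperatures are linearly interpolated
(constant extrapolation outside the listed range, with a logged warning when
no correction data exist at all).

Also provides the "conformer of interest" filter: a conformer matters if it is
among the ten lowest electronic-energy structures, or its equilibrium
concentration exceeds 1% at some temperature up to 450 K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import EnergyRecord

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "PopulationTable",
    "free_energy",
    "free_energies",
    "boltzmann_populations",
    "populations_vs_T",
    "select_conformers_of_interest",
]

log = logging.getLogger(__name__)

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA-derived, fixed).
KB_KCAL_PER_MOL_K = 1.98720425864083e-3


def _g_corr_at(record: EnergyRecord, T: float) -> float:
    """Free-energy correction at T: linear interpolation, constant extrapolation."""
    if not record.g_corr:
        log.warning(
            "no free-energy correction for %s; using g_corr = 0 at T = %g K",
            record.conformer_id,
            T,
        )
        return 0.0
    temps = np.array(sorted(record.g_corr))
    vals = np.array([record.g_corr[t] for t in temps])
    return float(np.interp(T, temps, vals))


def free_energy(e_rel: float, g_corr: float) -> float:
    """Relative free energy of one conformer before ensemble re-referencing."""
    return e_rel + g_corr


def free_energies(records: list[EnergyRecord], T: float) -> pd.Series:
    """Ensemble relative free energies at T, re-referenced so the minimum is 0."""
    if not records:
        raise ValueError("empty ensemble")
    g = pd.Series(
        {r.conformer_id: free_energy(r.e_rel, _g_corr_at(r, T)) for r in records},
        dtype=float,
    )
    return g - g.min()


def boltzmann_populations(g_rel, T: float):
    """Boltzmann fractions in percent for relative free energies (kcal/mol).

    Numerically stabilised by subtracting the minimum before exponentiation.
    Accepts a sequence or a pandas Series (the return type matches).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    g = np.asarray(g_rel, dtype=float)
    if g.size == 0:
        raise ValueError("empty ensemble")
    w = np.exp(-(g - g.min()) / (KB_KCAL_PER_MOL_K * T))
    p = 100.0 * w / w.sum()
    if isinstance(g_rel, pd.Series):
        return pd.Series(p, index=g_rel.index)
    return p


@dataclass
class PopulationTable:
    """Equilibrium populations (percent) over a temperature grid.

    ``table`` is indexed by conformer id with one column per temperature (K).
    Full precision is kept internally; :meth:`to_display` renders values below
    1% as an em dash, following the field's reporting convention.
    """

    table: pd.DataFrame
    kB: float = field(default=KB_KCAL_PER_MOL_K, repr=False)

    @property
    def temperatures(self) -> list[float]:
        return [float(t) for t in self.table.columns]

    @property
    def conformer_ids(self) -> list[str]:
        return list(self.table.index)

    def at(self, T: float) -> pd.Series:
        return self.table[T]

    def to_display(self, decimals: int = 2, below: float = 1.0) -> pd.DataFrame:
        def fmt(v: float) -> str:
            return "—" if v < below else f"{v:.{decimals}f}"

        return self.table.map(fmt)


def populations_vs_T(records: list[EnergyRecord], temps) -> PopulationTable:
    """Population table over all records for each requested temperature."""
    temps = [float(t) for t in temps]
    if any(t <= 0 for t in temps):
        raise ValueError("temperatures must be positive")
    cols = {}
    for T in temps:
        cols[T] = boltzmann_populations(free_energies(records, T), T)
    return PopulationTable(table=pd.DataFrame(cols))


def select_conformers_of_interest(
    records: list[EnergyRecord],
    pop_table: PopulationTable | None = None,
    n_lowest: int = 10,
    concentration_threshold: float = 1.0,
    t_max: float = 450.0,
) -> list[str]:
    """Conformers of interest: ten lowest e_rel, or > 1% somewhere up to 450 K.

    When ``pop_table`` is omitted, populations are computed on a 10-450 K grid
    in 10 K steps. Result order follows ascending electronic energy.
    """
    if not records:
        return []
    if pop_table is None:
        pop_table = populations_vs_T(records, np.arange(10.0, t_max + 1e-9, 10.0))
    by_energy = sorted(records, key=lambda r: (r.e_rel, r.conformer_id))
    chosen = {r.conformer_id for r in by_energy[:n_lowest]}
    temps = [t for t in pop_table.temperatures if t <= t_max]
    if temps:
        sub = pop_table.table[temps]
        chosen |= set(sub.index[(sub > concentration_threshold).any(axis=1)])
    return [r.conformer_id for r in by_energy if r.conformer_id in chosen]
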