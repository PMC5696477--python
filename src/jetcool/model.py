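"""Model/results facade over the jet-cooling analysis pipeline.

:class:`JetCoolingModel` bundles the inputs of a study — an energy table,
structural types, optional explicit barriers — together with the physical
parameters (effective pre-expansion temperature, low-temperature reference,
barrier-class boundaries, observability threshold). :meth:`JetCoolingModel.fit`
runs the pipeline (equilibrium populations -> low-barrier conversion graph ->
kinetic pooling -> observability) and returns a :class:`JetCoolingResults`
carrying the population table, the basins and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble_io, kinetics, thermo
from .ensemble_io import BarrierRecord, EnergyRecord
from .kinetics import (
    HIGH_BARRIER_MIN,
    LOW_BARRIER_MAX,
    OBSERVABLE_THRESHOLD,
    T_EFF_DEFAULT,
    T_REF_DEFAULT,
    BasinResult,
)
from .structure import StructuralType

__all__ = ["JetCoolingModel", "JetCoolingResults"]


@dataclass
class JetCoolingModel:
    """Kinetic-trapping model of a conformer ensemble under jet cooling.

    Parameters
    ----------
    energies
        Energy records (relative kcal/mol, optional per-temperature
        free-energy corrections).
    types
        Structural types by conformer id; used to predict barrier classes for
        pairs without an explicit barrier.
    barriers
        Explicit conversion barriers (kcal/mol); always override the
        type-based prediction.
    t_eff, t_ref
        Effective pre-expansion temperature (K) and post-expansion reference
        temperature for sink selection.
    populations_at_teff, g_at_tref
        Optional overrides when populations / low-temperature free energies
        come from an external table instead of the energy records.
    """

    energies: list[EnergyRecord]
    types: dict[str, StructuralType] | None = None
    barriers: list[BarrierRecord] | None = None
    t_eff: float = T_EFF_DEFAULT
    t_ref: float = T_REF_DEFAULT
    low_barrier_max: float = LOW_BARRIER_MAX
    high_barrier_min: float = HIGH_BARRIER_MIN
    observable_threshold: float = OBSERVABLE_THRESHOLD
    populations_at_teff: dict[str, float] | None = None
    g_at_tref: dict[str, float] | None = None

    @classmethod
    def from_tables(
        cls,
        energy_path,
        types_path=None,
        barrier_path=None,
        **kwargs,
    ) -> "JetCoolingModel":
        """Build a model from delimited files (energies, optional types CSV
        with columns conformer/type, optional barrier table)."""
        energies = ensemble_io.read_energy_table(energy_path)
        types = None
        if types_path is not None:
            df = pd.read_csv(types_path)
            cols = {c.lower(): c for c in df.columns}
            idc = cols.get("conformer", df.columns[0])
            tyc = cols.get("type", df.columns[1])
            types = {
                str(r[idc]): StructuralType.from_label(str(r[tyc]))
                for _, r in df.iterrows()
            }
        barriers = (
            ensemble_io.read_barrier_table(barrier_path) if barrier_path else None
        )
        return cls(energies=energies, types=types, barriers=barriers, **kwargs)

    @property
    def conformer_ids(self) -> list[str]:
        return [r.conformer_id for r in self.energies]

    def fit(self, temperatures=None) -> "JetCoolingResults":
        """Run the pipeline and return the fitted results.

        ``temperatures`` extends the reported population grid (t_eff and t_ref
        are always included).
        """
        temps = sorted({self.t_ref, self.t_eff, *(temperatures or ())})
        pop_table = thermo.populations_vs_T(self.energies, temps)
        pops = (
            dict(self.populations_at_teff)
            if self.populations_at_teff is not None
            else pop_table.at(self.t_eff).to_dict()
        )
        g_ref = (
            dict(self.g_at_tref)
            if self.g_at_tref is not None
            else thermo.free_energies(self.energies, self.t_ref).to_dict()
        )
        graph = kinetics.build_conversion_graph(
            self.conformer_ids,
            types=self.types,
            barriers=self.barriers,
            low_max=self.low_barrier_max,
            high_min=self.high_barrier_min,
        )
        basins = kinetics.pool_populations(
            graph,
            pops,
            g_at_tref=g_ref,
            e_rel={r.conformer_id: r.e_rel for r in self.energies},
            observable_threshold=self.observable_threshold,
        )
        return JetCoolingResults(model=self, populations=pop_table, basins=basins)


@dataclass
class JetCoolingResults:
    """Fitted jet-cooling analysis: populations, kinetic basins, observability."""

    model: JetCoolingModel
    populations: thermo.PopulationTable
    basins: list[BasinResult] = field(default_factory=list)

    @property
    def observable(self) -> list[tuple[str, float]]:
        """(sink, pooled %) pairs above the observability threshold."""
        return kinetics.observable_conformers(
            self.basins, self.model.observable_threshold
        )

    @property
    def n_observable(self) -> int:
        return len(self.observable)

    def basin_of(self, conformer_id: str) -> BasinResult:
        for b in self.basins:
            if conformer_id in b.members:
                return b
        raise KeyError(conformer_id)

    def to_report(self, path) -> None:
        ensemble_io.write_report(self.basins, path)

    def summary(self) -> str:
        """Human-readable account of the pooled ensemble."""
        m = self.model
        lines = [
            "Jet-cooling kinetic pooling",
            "===========================",
            f"conformers: {len(m.conformer_ids)}   basins: {len(self.basins)}   "
            f"observable: {self.n_observable}",
            f"T_eff = {m.t_eff:g} K   T_ref = {m.t_ref:g} K   "
            f"barrier classes: low <= {m.low_barrier_max:g}, "
            f"high >= {m.high_barrier_min:g} kcal/mol   "
            f"threshold = {m.observable_threshold:g}%",
            "",
            f"{'sink':<10}{'pooled %':>10}{'obs':>6}  members",
            "-" * 60,
        ]
        for b in self.basins:
            members = " ".join(sorted(b.members, key=_natural_key))
            lines.append(
                f"{b.sink:<10}{b.pooled_population:>10.2f}"
                f"{'  *' if b.observable else '':>6}  {members}"
            )
        lines.append("-" * 60)
        total = sum(b.pooled_population for b in self.basins)
        lines.append(f"{'total':<10}{total:>10.2f}")
        return "\n".join(lines)

    def plot_populations(self, ax=None):
        """Equilibrium populations vs temperature, one line per conformer."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.populations.temperatures
        for cid in self.populations.conformer_ids:
            ax.plot(t, self.populations.table.loc[cid], label=cid, lw=1)
        ax.set_xlabel("temperature / K")
        ax.set_ylabel("equilibrium population / %")
        if len(self.populations.conformer_ids) <= 12:
            ax.legend(fontsize="small")
        return ax


def _natural_key(s: str):
    import re

    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]
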