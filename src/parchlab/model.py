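"""Model/Results interface over the parch estimator and the zonation step.

``ParchModel`` is constructed from replicate contact trajectories plus a
lysine reference and its :meth:`fit` returns :class:`ParchResults` carrying
per-residue estimates, replicate spread and a ``summary()`` table.
``ZonationModel`` wraps the k-means zone assignment the same way.  Both are
thin, stateful fronts over the functional modules, so scripted pipelines can
use either style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import (
    AnnealingSchedule,
    ContactTrajectory,
    ParchResult,
    parch_pipeline,
    reference_c_bar,
)
from .errors import ParameterError
from .structure import ProteinStructure
from .zonation import (
    ZoneAssignment,
    ZoneFeatures,
    cluster_zones,
    zone_fractions,
    zone_parch_summary,
)

__all__ = ["ParchModel", "ParchResults", "ZonationModel", "ZonationResults"]


class ParchModel:
    """Parch hydropathy estimator for one protein.

    Parameters
    ----------
    trajectories : list of ContactTrajectory
        Annealing replicates over the same structure and schedule (three by
        protocol; pass ``strict_triplicate=False`` to fit any n ≥ 1).
    reference : float or ContactTrajectory
        The lysine normalization constant C̄_Lys, either precomputed or as the
        isolated-lysine trajectory it is derived from.
    structure : ProteinStructure, optional
        When given, results are annotated with chain/position/type.
    """

    def __init__(self, trajectories: list[ContactTrajectory],
                 reference, structure: ProteinStructure | None = None,
                 strict_triplicate: bool = True):
        if not trajectories:
            raise ParameterError("at least one replicate trajectory is required")
        self.trajectories = list(trajectories)
        self.structure = structure
        self.strict_triplicate = strict_triplicate
        self.schedule: AnnealingSchedule = trajectories[0].schedule
        if isinstance(reference, ContactTrajectory):
            self.reference_c_bar = reference_c_bar(reference, self.schedule)
        else:
            self.reference_c_bar = float(reference)

    @classmethod
    def from_world(cls, world) -> "ParchModel":
        """Build from a :class:`parchlab.synthetic.SyntheticWorld`."""
        return cls(list(world.trajectories), world.reference_c_bar,
                   structure=world.structure)

    def fit(self) -> "ParchResults":
        results = parch_pipeline(self.trajectories, self.reference_c_bar,
                                 strict_triplicate=self.strict_triplicate)
        return ParchResults(model=self, results=results)


@dataclass
class ParchResults:
    """Fitted per-residue parch values with replicate uncertainties."""

    model: ParchModel
    results: list[ParchResult]

    @property
    def parch(self) -> np.ndarray:
        return np.asarray([r.parch for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        """Per-residue table (chain/position/type columns when a structure is attached)."""
        rows = []
        structure = self.model.structure
        for r in self.results:
            row = {"residue_index": r.residue_index}
            if structure is not None:
                res = structure.residues[r.residue_index]
                row.update(chain=res.chain_id, seq_index=res.seq_index,
                           aa_type=res.aa_type)
            row.update(C_bar=r.C_bar, parch=r.parch, parch_sd=r.parch_sd)
            for k, v in enumerate(r.parch_replicates, start=1):
                row[f"parch_rep{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Parch hydropathy estimates",
            "=" * 60,
            f"residues: {len(df)}    replicates: {len(self.model.trajectories)}",
            f"reference C_bar (Lys): {self.model.reference_c_bar:.4f}",
            f"parch range: [{df['parch'].min():.2f}, {df['parch'].max():.2f}]"
            f"    median: {df['parch'].median():.2f}",
            f"zero-parch residues: {(df['parch'] == 0).sum()}",
            "-" * 60,
        ]
        with pd.option_context("display.max_rows", 20, "display.width", 100):
            lines.append(df.to_string(index=False, float_format=lambda x: f"{x:.3f}",
                                      max_rows=20))
        return "\n".join(lines)

    def zone_summary(self, assignment: ZoneAssignment) -> dict:
        return zone_parch_summary(self.results, assignment)

    def plot_distribution(self, ax=None, bins=None):
        """Histogram of fitted parch values (convenience output)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if bins is None:
            bins = np.arange(0.0, 10.0 + 0.1, 0.1)
        ax.hist(self.parch, bins=bins, density=True)
        ax.set_xlabel("parch value")
        ax.set_ylabel("density")
        return ax


class ZonationModel:
    """k-means shell/mantle/core assignment from topographic features."""

    def __init__(self, features: list[ZoneFeatures]):
        self.features = list(features)

    def fit(self, seed: int = 0, on_degenerate: str = "raise") -> "ZonationResults":
        assignment = cluster_zones(self.features, seed=seed,
                                   on_degenerate=on_degenerate)
        return ZonationResults(model=self, assignment=assignment)


@dataclass
class ZonationResults:
    model: ZonationModel
    assignment: ZoneAssignment

    @property
    def fractions(self) -> tuple[float, float, float]:
        return zone_fractions(self.assignment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue_index": f.residue_index, "n_water": f.n_water,
             "n_neighbors": f.n_neighbors,
             "zone": self.assignment.zones[f.residue_index]}
            for f in self.model.features
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        shell, mantle, core = self.fractions
        lines = [
            "Shell/mantle/core zonation (k-means, k=3)",
            "=" * 60,
            f"residues: {len(self.assignment.zones)}"
            + ("    [degenerate: single zone]" if self.assignment.degenerate else ""),
            f"fractions: shell {shell:.1f}%  mantle {mantle:.1f}%  core {core:.1f}%",
        ]
        for zone, (w, nb) in self.assignment.centroids.items():
            lines.append(f"centroid[{zone}]: n_water {w:.2f}, n_neighbors {nb:.2f}")
        return "\n".join(lines)
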