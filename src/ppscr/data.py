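"""In-memory containers for activity centers and detection records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ACSet", "DetectionData"]


@dataclass
class ACSet:
    """Continuous activity-center coordinates (latent or simulated).

    ``observed`` flags individuals with at least one detection; it is filled
    by the simulator's truth table and is all-True by default.
    """

    coords: np.ndarray  # (N, 2) km
    ids: list[str] = field(default_factory=list)
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(len(self.coords))]
        if self.observed is None:
            self.observed = np.ones(len(self.coords), dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "observed": self.observed.astype(int),
            }
        )


class DetectionData:
    """Per-individual sets of continuous detection locations.

    Each observed individual has one or more planar detection coordinates
    (km).  Individuals with zero detections never appear here — they are the
    latent part of the model.
    """

    def __init__(self, ids: list[str], locations: list[np.ndarray]) -> None:
        if len(ids) != len(set(ids)):
            raise ValueError("individual ids must be unique")
        if len(ids) != len(locations):
            raise ValueError("ids and locations differ in length")
        self.ids = list(ids)
        self.locations = [np.asarray(loc, dtype=float).reshape(-1, 2) for loc in locations]

    @property
    def n_observed(self) -> int:
        return sum(1 for loc in self.locations if len(loc) > 0)

    @property
    def counts(self) -> np.ndarray:
        """M_i, the number of detections of each individual."""
        return np.array([len(loc) for loc in self.locations], dtype=int)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.locations))

    def validate_in_grid(self, detgrid) -> None:
        """Every detection must lie inside some detection window."""
        for ind, loc in self:
            if len(loc) == 0:
                continue
            inside = detgrid.contains(loc)
            if not inside.all():
                bad = loc[np.argmax(~inside)]
                raise ValueError(
                    f"detection {tuple(bad)} of individual {ind!r} lies outside "
                    "every detection window"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, loc in self:
            for x, y in loc:
                rows.append((ind, x, y))
        return pd.DataFrame(rows, columns=["individual_id", "x", "y"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DetectionData":
        required = {"individual_id", "x", "y"}
        if not required.issubset(df.columns):
            raise ValueError(f"detections table needs columns {sorted(required)}")
        ids, locs = [], []
        for ind, grp in df.groupby("individual_id", sort=False):
            ids.append(str(ind))
            locs.append(grp[["x", "y"]].to_numpy(float))
        return cls(ids, locs)

    @classmethod
    def from_csv(cls, path) -> "DetectionData":
        return cls.from_frame(pd.read_csv(path))
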