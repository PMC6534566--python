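"""ROI parcellation: ordered ROIs with resting-state network labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI list with one network label per ROI.

    The ROI order is fixed and shared by every matrix in the analysis
    (time series columns, FC rows/columns). Each ROI belongs to exactly
    one resting-state network; optionally each ROI also carries a finer
    subnetwork label used for finer-grained block analyses.
    """

    roi_ids: tuple[str, ...]
    networks: tuple[str, ...]
    subnetworks: tuple[str, ...] | None = None
    network_order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.roi_ids) != len(self.networks):
            raise ValueError("roi_ids and networks must have equal length")
        if self.subnetworks is not None and len(self.subnetworks) != len(self.roi_ids):
            raise ValueError("subnetworks length mismatch")
        if len(set(self.networks)) < 2:
            raise ValueError("parcellation must cover at least two networks")
        if not self.network_order:
            seen: list[str] = []
            for n in self.networks:
                if n not in seen:
                    seen.append(n)
            object.__setattr__(self, "network_order", tuple(seen))

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    def indices(self, network: str, level: str = "network") -> np.ndarray:
        """Index array of the ROIs belonging to one (sub)network."""
        labels = self.labels(level)
        idx = np.flatnonzero(np.asarray(labels) == network)
        if idx.size == 0:
            raise KeyError(f"unknown or empty {level} label: {network!r}")
        return idx

    def labels(self, level: str = "network") -> tuple[str, ...]:
        if level == "network":
            return self.networks
        if level == "subnetwork":
            if self.subnetworks is None:
                raise ValueError("parcellation has no subnetwork labels")
            return self.subnetworks
        raise ValueError(f"unknown level: {level!r}")

    def label_order(self, level: str = "network") -> tuple[str, ...]:
        labels = self.labels(level)
        seen: list[str] = []
        for n in labels:
            if n not in seen:
                seen.append(n)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"roi_id": self.roi_ids, "network": self.networks})
        df["subnetwork"] = self.subnetworks if self.subnetworks is not None else ""
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        sub = None
        if "subnetwork" in df.columns:
            vals = df["subnetwork"].fillna("").astype(str)
            if (vals != "").any():
                sub = tuple(vals)
        return cls(
            roi_ids=tuple(df["roi_id"].astype(str)),
            networks=tuple(df["network"].astype(str)),
            subnetworks=sub,
        )


def make_parcellation(
    n_roi: int,
    network_sizes: dict[str, int],
    subnetworks_per_network: int = 1,
) -> Parcellation:
    """Assign ROIs contiguously to networks in the given order.

    Parameters
    ----------
    n_roi
        Total number of ROIs; must equal the sum of ``network_sizes``.
    network_sizes
        Mapping network label -> ROI count, in the desired order.
    subnetworks_per_network
        If > 1, each network is split into that many contiguous
        subnetworks labeled ``<net>-1 .. <net>-k`` (mimicking a
        finer-grained parcellation of the same cortex).
    """
    if n_roi <= 0:
        raise ValueError("n_roi must be positive")
    total = sum(network_sizes.values())
    if total != n_roi:
        raise ValueError(f"network sizes sum to {total}, expected {n_roi}")
    if any(c <= 0 for c in network_sizes.values()):
        raise ValueError("network sizes must be positive")

    networks: list[str] = []
    subnets: list[str] = []
    for label, count in network_sizes.items():
        networks.extend([label] * count)
        if subnetworks_per_network > 1:
            # contiguous near-equal split of the network's ROIs
            edges = np.linspace(0, count, subnetworks_per_network + 1).round().astype(int)
            for k in range(subnetworks_per_network):
                subnets.extend([f"{label}-{k + 1}"] * (edges[k + 1] - edges[k]))
        else:
            subnets.extend([label] * count)
    roi_ids = tuple(f"ROI{i + 1:03d}" for i in range(n_roi))
    return Parcellation(
        roi_ids=roi_ids,
        networks=tuple(networks),
        subnetworks=tuple(subnets),
    )
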