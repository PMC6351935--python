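"""Enhanced two-step floating catchment area (E2SFCA) accessibility and
Spatial Access Ratio (SPAR) normalization.

The method measures potential spatial access of a population location to
service facilities over a travel-time network:

Step 1 (supply): each facility j with capacity S_j gets a
provider-to-population ratio

    R_j = S_j / sum_k P_k * W(t_kj),   over population points k with
                                       t_kj <= D_max,

where the catchment (default 30 min) is divided into travel-time
subzones with stepwise distance-decay weights W_r (default zones
[0-10], (10-20], (20-30] min with weights 1.00, 0.42, 0.09 — the sharp
urban decay).

Step 2 (demand): each population location i sums the decay-weighted
ratios of facilities it can reach:

    A_i = sum_j R_j * W(t_ij),   over facilities with t_ij <= D_max.

SPAR_i = A_i / mean(A) normalizes out the decay-parameter scale; its
mean over all population locations is 1 by construction.  Locations with
SPAR = 0 (no facility reachable within the catchment) are shortage
areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .network import NetworkError, TravelNetwork, one_to_many_times, snap_point

__all__ = [
    "DecayScheme",
    "Facility",
    "PopulationPoint",
    "FacilityRatio",
    "AccessRecord",
    "zone_weight",
    "step1_provider_ratio",
    "step2_accessibility",
    "spar",
    "classify_quantiles",
    "shortage_summary",
    "accessibility_analysis",
]


@dataclass(frozen=True)
class DecayScheme:
    """Stepwise distance-decay: catchment breaks (minutes) and weights."""

    zone_breaks: Tuple[float, ...] = (10.0, 20.0, 30.0)
    weights: Tuple[float, ...] = (1.00, 0.42, 0.09)

    def __post_init__(self) -> None:
        br, w = self.zone_breaks, self.weights
        if len(br) != len(w):
            raise ValueError("zone_breaks and weights must have equal length")
        if any(b <= 0 for b in br) or any(b1 <= b0 for b0, b1 in zip(br, br[1:])):
            raise ValueError("zone_breaks must be positive and strictly increasing")
        if any(not (0 < x <= 1) for x in w) or any(w1 >= w0 for w0, w1 in zip(w, w[1:])):
            raise ValueError("weights must be strictly decreasing in (0, 1]")

    @property
    def cutoff_min(self) -> float:
        return self.zone_breaks[-1]


@dataclass
class Facility:
    """Service facility with provider capacity S_j."""

    id: str
    location: Tuple[float, float]
    providers: float

    def __post_init__(self) -> None:
        if self.providers < 0:
            raise ValueError(f"facility {self.id!r}: providers must be >= 0")


@dataclass
class PopulationPoint:
    """Population-weighted centroid of a census unit."""

    id: str
    location: Tuple[float, float]
    population: float
    area_km2: float = 1.0
    covariates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"population point {self.id!r}: population must be >= 0")
        if self.area_km2 <= 0:
            raise ValueError(f"population point {self.id!r}: area must be positive")


@dataclass
class FacilityRatio:
    facility_id: str
    r_j: float
    catchment_empty: bool = False


@dataclass
class AccessRecord:
    location_id: str
    a_index: float
    spar: float = float("nan")
    quantile_class: str = ""


def zone_weight(t: float, scheme: DecayScheme = DecayScheme()) -> float:
    """Decay weight for a travel time: W_1 on [0, D_1], W_r on
    (D_{r-1}, D_r], 0 beyond the catchment."""
    if t < 0:
        raise ValueError(f"travel time must be >= 0, got {t}")
    for b, w in zip(scheme.zone_breaks, scheme.weights):
        if t <= b + 1e-9:
            return w
    return 0.0


def step1_provider_ratio(facility: Facility,
                         times: Mapping[str, float],
                         populations: Mapping[str, PopulationPoint],
                         scheme: DecayScheme = DecayScheme()) -> FacilityRatio:
    """Provider-to-population ratio R_j = S_j / sum P_k W(t_kj).

    ``times`` maps population-point id -> travel time (minutes) from the
    facility; points missing from it or beyond the catchment do not
    contribute.  A facility with an empty catchment gets R_j = 0 and is
    flagged.
    """
    denom = 0.0
    for pid, t in times.items():
        w = zone_weight(t, scheme)
        if w > 0:
            denom += populations[pid].population * w
    if denom <= 0:
        return FacilityRatio(facility.id, 0.0, catchment_empty=True)
    return FacilityRatio(facility.id, facility.providers / denom)


def step2_accessibility(location: PopulationPoint,
                        ratios: Mapping[str, FacilityRatio],
                        times: Mapping[str, float],
                        scheme: DecayScheme = DecayScheme()) -> float:
    """Accessibility index A_i = sum_j R_j W(t_ij) over reachable
    facilities."""
    a = 0.0
    for fid, t in times.items():
        w = zone_weight(t, scheme)
        if w > 0:
            a += ratios[fid].r_j * w
    return a


def spar(a_indices: Sequence[float]) -> np.ndarray:
    """Spatial Access Ratios: each index divided by the unweighted mean
    over ALL population locations (zeros included)."""
    a = np.asarray(a_indices, dtype=float)
    if a.size == 0 or not np.any(a > 0):
        raise ValueError("SPAR undefined: all accessibility indices are zero")
    if np.any(a < 0):
        raise ValueError("accessibility indices must be >= 0")
    return a / a.mean()


def classify_quantiles(spars: Sequence[float], n_classes: int = 5,
                       ids: Optional[Sequence[str]] = None) -> List[str]:
    """Quantile classes of the positive SPAR values, zeros isolated.

    Zero values are labelled ``"no access"``; positive values are split
    into ``n_classes`` equal-count rank groups ``Q1`` (lowest) ..
    ``Q<n>`` (highest), ties broken by location-id order for stability.
    """
    vals = list(spars)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(vals))]
    labels = ["no access"] * len(vals)
    pos = [i for i, v in enumerate(vals) if v > 0]
    if not pos:
        return labels
    pos.sort(key=lambda i: (vals[i], ids[i]))
    n_pos = len(pos)
    for rank, i in enumerate(pos):
        cls = min(n_classes - 1, rank * n_classes // n_pos)
        labels[i] = f"Q{cls + 1}"
    return labels


def shortage_summary(records: Sequence[AccessRecord],
                     populations: Mapping[str, PopulationPoint]) -> Dict[str, float]:
    """Aggregate shortage (SPAR = 0) areas: km², population, and percent
    of total population (percent reported unrounded; display rounds to
    one decimal)."""
    rec_ids = {r.location_id for r in records}
    if rec_ids != set(populations):
        raise ValueError("records and populations must cover the same ids")
    total_pop = sum(p.population for p in populations.values())
    area = sum(populations[r.location_id].area_km2 for r in records if r.spar == 0)
    pop = sum(populations[r.location_id].population for r in records if r.spar == 0)
    pct = 100.0 * pop / total_pop if total_pop > 0 else 0.0
    return {"area_km2": area, "population": pop, "percent_of_total": pct}


def accessibility_analysis(network: TravelNetwork,
                           facilities: Sequence[Facility],
                           populations: Sequence[PopulationPoint],
                           scheme: DecayScheme = DecayScheme(),
                           snap_max_dist_m: float = 500.0,
                           n_classes: int = 5,
                           ) -> Tuple[List[AccessRecord], List[FacilityRatio]]:
    """Run both E2SFCA steps plus SPAR and quantile classes on a network.

    Facilities and population points are snapped to their nearest network
    node; travel times are computed by one shortest-path sweep per
    facility (the network is undirected, so facility→population times
    equal population→facility times).
    """
    pop_by_id = {p.id: p for p in populations}
    pop_nodes: Dict[str, str] = {}
    for p in populations:
        node = snap_point(network, p.location, snap_max_dist_m)
        if node is None:
            raise NetworkError(
                f"population point {p.id!r} has no network node within "
                f"{snap_max_dist_m} m"
            )
        pop_nodes[p.id] = node
    node_to_pops: Dict[str, List[str]] = {}
    for pid, node in pop_nodes.items():
        node_to_pops.setdefault(node, []).append(pid)

    fac_times: Dict[str, Dict[str, float]] = {}
    ratios: List[FacilityRatio] = []
    for fac in facilities:
        node = snap_point(network, fac.location, snap_max_dist_m)
        if node is None:
            raise NetworkError(
                f"facility {fac.id!r} has no network node within "
                f"{snap_max_dist_m} m"
            )
        reach = one_to_many_times(network, node, scheme.cutoff_min)
        times = {
            pid: t
            for n, t in reach.items()
            for pid in node_to_pops.get(n, ())
        }
        fac_times[fac.id] = times
        ratios.append(step1_provider_ratio(fac, times, pop_by_id, scheme))

    ratio_by_id = {r.facility_id: r for r in ratios}
    records = []
    for p in populations:
        times_to_fac = {
            fid: t[p.id] for fid, t in fac_times.items() if p.id in t
        }
        a = step2_accessibility(p, ratio_by_id, times_to_fac, scheme)
        records.append(AccessRecord(location_id=p.id, a_index=a))

    spars = spar([r.a_index for r in records])
    labels = classify_quantiles(spars, n_classes, ids=[r.location_id for r in records])
    for rec, s, lab in zip(records, spars, labels):
        rec.spar = float(s)
        rec.quantile_class = lab
    return records, ratios
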