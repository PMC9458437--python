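"""In-silico TetR/GFP two-plasmid compatibility assay and readout layer.

The screening circuit: a reporter plasmid carries GFP behind the P_tetA
promoter; a regulatory plasmid carries TetR.  While both plasmids are
present GFP is repressed; losing the regulatory plasmid derepresses the
promoter and the cell lights up.  With antibiotic selection kept on the
reporter plasmid, bulk fluorescence (normalised by culture density) is a
direct readout of regulatory-plasmid loss — i.e. of origin incompatibility
in one direction.  Swapping which origin sits on which plasmid probes the
other direction, and the two need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .lv import LVParams, from_copy_numbers
from .segregation import (
    PassagingProtocol,
    Population,
    RetentionCurve,
    initial_population,
    serial_passage,
)

__all__ = [
    "NoiseModel",
    "PlateReading",
    "CompatibilityMatrix",
    "reporter_state",
    "gfp_on_fraction",
    "well_readout",
    "normalized_fluorescence",
    "cross_compat_matrix",
    "gate_events",
    "orthogonality_score",
    "pair_params",
]


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: endpoint OD600 and fluorescence model.

    od600 = od_per_cell * live cells; fluorescence = background +
    signal_per_cell * (#GFP-on cells) + N(0, noise_sd), truncated at 0.
    Presets for different media differ only in background/noise levels.
    """

    background_mean: float = 50.0
    noise_sd: float = 0.0
    signal_per_cell: float = 10.0
    od_per_cell: float = 1e-4


#: Media presets: minimal medium gives the lowest, tightest background.
MEDIA_PRESETS: dict[str, NoiseModel] = {
    "LB": NoiseModel(background_mean=200.0, noise_sd=40.0),
    "M9": NoiseModel(background_mean=50.0, noise_sd=8.0),
}


@dataclass(frozen=True)
class PlateReading:
    well: str
    od600: float
    fluorescence: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.od600 < 0 or self.fluorescence < 0:
            raise ValueError("od600 and fluorescence must be non-negative")


@dataclass
class CompatibilityMatrix:
    """Ordered-pair grid: rows = reporter origin (under selection),
    columns = regulatory origin (free to be lost)."""

    origin_ids: tuple[str, ...]
    retention: NDArray[np.float64]      # regulatory retention at assay end
    fluorescence: NDArray[np.float64]   # normalised endpoint fluorescence
    calls: NDArray  # "compatible" / "incompatible"
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.origin_ids)
        for i in range(n):
            for j in range(n):
                rows.append({
                    "reporter": self.origin_ids[i],
                    "regulatory": self.origin_ids[j],
                    "retention": float(self.retention[i, j]),
                    "norm_fluorescence": float(self.fluorescence[i, j]),
                    "call": str(self.calls[i, j]),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-cell reporter logic

def reporter_state(
    cell: Sequence[int] | NDArray, reporter_idx: int, regulatory_idx: int
) -> bool:
    """GFP on iff the regulatory plasmid is lost and the reporter is present.

    No TetR dilution lag is modelled: readouts are >= 24 h endpoints and
    derepression is fast on that scale.
    """
    copies = np.asarray(cell)
    return bool(copies[regulatory_idx] == 0 and copies[reporter_idx] >= 1)


def gfp_on_fraction(
    pop: Population, reporter_idx: int, regulatory_idx: int
) -> float:
    if pop.n_cells == 0:
        return 0.0
    on = (pop.copies[:, regulatory_idx] == 0) & (pop.copies[:, reporter_idx] >= 1)
    return float(on.mean())


# ---------------------------------------------------------------------------
# plate readout

def well_readout(
    pop: Population,
    reporter_idx: int,
    regulatory_idx: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    well: str = "A1",
    metadata: dict | None = None,
) -> PlateReading:
    """Endpoint plate-reader measurement of one well."""
    n_on = int(
        ((pop.copies[:, regulatory_idx] == 0) & (pop.copies[:, reporter_idx] >= 1)).sum()
    ) if pop.n_cells else 0
    od = noise.od_per_cell * pop.n_cells
    fl = noise.background_mean + noise.signal_per_cell * n_on
    if noise.noise_sd > 0:
        fl += rng.normal(0.0, noise.noise_sd)
    return PlateReading(
        well=well,
        od600=max(od, 0.0),
        fluorescence=max(fl, 0.0),
        metadata=metadata or {},
    )


def normalized_fluorescence(
    reading: PlateReading, background: float = 0.0, od_floor: float = 1e-6
) -> float:
    """(fluorescence - background) / od600; rejects effectively empty wells."""
    if reading.od600 < od_floor:
        raise ValueError(
            f"od600 {reading.od600:g} below floor {od_floor:g} (empty well)"
        )
    return (reading.fluorescence - background) / reading.od600


# ---------------------------------------------------------------------------
# cross-compatibility matrix

def pair_params(
    K_reporter: float,
    K_regulatory: float,
    c_rep_reg: float = 0.0,
    c_reg_rep: float = 0.0,
    r: float = 5.0,
    ids: tuple[str, str] = ("reporter", "regulatory"),
    self_pair: bool = False,
) -> LVParams:
    """Two-origin LV parameters for one ordered assay pair.

    Index 0 is the reporter (selected) origin, index 1 the regulatory one.
    ``self_pair=True`` models the same origin on both plasmids: the two
    populations share one copy-number control pool, i.e. the cross terms
    equal the self-limitation (-1/K both ways) and the LV system is
    degenerate along the line X1 + X2 = K.
    """
    if self_pair:
        c_rep_reg = -1.0 / K_regulatory
        c_reg_rep = -1.0 / K_reporter
    interaction = np.array([[0.0, c_rep_reg], [c_reg_rep, 0.0]])
    return from_copy_numbers(
        [K_reporter, K_regulatory], interaction, r=r, origin_ids=ids
    )


def cross_compat_matrix(
    K: Sequence[float],
    interaction: NDArray[np.float64],
    protocol: PassagingProtocol | None = None,
    rng: np.random.Generator | None = None,
    threshold: float = 0.5,
    n_cells: int = 1000,
    origin_ids: Sequence[str] = (),
    noise: NoiseModel = NoiseModel(),
) -> CompatibilityMatrix:
    """Simulate the full ordered-pair compatibility screen.

    For every ordered pair (reporter i, regulatory j) a two-origin system
    is passaged under selection on the reporter; the pair is called
    incompatible when regulatory retention at assay end falls below
    ``threshold``.  Diagonal (self vs self) pairs share a single replication
    control pool and are incompatible by definition of an incompatibility
    group: their call is forced regardless of the simulated fraction.
    """
    K = np.asarray(K, dtype=float)
    n = K.size
    interaction = np.asarray(interaction, dtype=float)
    if interaction.shape != (n, n):
        raise ValueError("interaction shape mismatch")
    if protocol is None:
        protocol = PassagingProtocol(selection=frozenset({0}))
    if 0 not in protocol.selection:
        raise ValueError("assay requires selection on the reporter origin (index 0)")
    if rng is None:
        rng = np.random.default_rng(0)
    ids = tuple(origin_ids) or tuple(f"ori{i}" for i in range(n))

    retention = np.zeros((n, n))
    fluor = np.zeros((n, n))
    calls = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            params = pair_params(
                K[i], K[j],
                c_rep_reg=interaction[i, j] if i != j else 0.0,
                c_reg_rep=interaction[j, i] if i != j else 0.0,
                ids=(ids[i], ids[j]),
                self_pair=(i == j),
            )
            pop0 = initial_population(n_cells, params.K, rng)
            curve = serial_passage(pop0, protocol, params, rng)
            ret = float(curve.fractions[-1, 1])  # regulatory origin
            retention[i, j] = ret
            final = curve.final_population
            reading = well_readout(final, 0, 1, noise, rng, well=f"{ids[i]}x{ids[j]}")
            try:
                fluor[i, j] = normalized_fluorescence(
                    reading, background=noise.background_mean
                )
            except ValueError:
                fluor[i, j] = np.nan
            if i == j:
                calls[i, j] = "incompatible"
            else:
                calls[i, j] = "compatible" if ret >= threshold else "incompatible"
    return CompatibilityMatrix(
        origin_ids=ids, retention=retention, fluorescence=fluor,
        calls=calls, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# flow cytometry and scoring

def gate_events(
    events: Sequence[float] | NDArray,
    gate_threshold: float,
    min_events: int = 1300,
) -> float:
    """Fraction of per-cell fluorescence events above the gate.

    A minimum event count (default 1300) is enforced so the fraction is
    statistically meaningful.
    """
    ev = np.asarray(events, dtype=float)
    if ev.size < min_events:
        raise ValueError(f"need >= {min_events} events, got {ev.size}")
    return float((ev > gate_threshold).mean())


def orthogonality_score(
    curve: RetentionCurve, origin_idx: int = 1, threshold: float = 0.5
) -> float:
    """Passages survived before the unselected origin's retention < 0.5.

    Linear interpolation between recorded passages gives a continuous
    score; a curve that never crosses the threshold scores the protocol
    length (compatibility capped at the assay horizon).  Monotone in
    compatibility: weaker interference -> slower loss -> higher score.
    """
    frac = curve.fractions[:, origin_idx]
    passages = curve.passage.astype(float)
    for k in range(1, len(frac)):
        if frac[k] < threshold:
            f0, f1 = frac[k - 1], frac[k]
            if f0 <= threshold:
                return float(passages[k - 1])
            # interpolate the crossing within the passage interval
            t = (f0 - threshold) / (f0 - f1)
            return float(passages[k - 1] + t * (passages[k] - passages[k - 1]))
    if frac[0] < threshold:
        return 0.0
    return float(passages[-1])
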