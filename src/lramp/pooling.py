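"""Stoichiometry calculators for LR amplicon library preparation.

Covers the deterministic arithmetic of the wet-lab protocol: C1V1 = C2V2
dilutions, size-proportional amplicon pooling (so every template copy,
regardless of amplicon length, contributes the same molar amount), dsDNA
molarity from mass concentration and mean fragment size, target-size-
proportional pooling of indexed libraries, and exome spike-in amounts from
the target-region ratio.

Volumes are rounded to 0.1 uL (a pipettable increment); the rounding
residue is assigned to the largest component so plan totals are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

from .intervals import ValidationError

#: average molar mass of one double-stranded base pair, g/mol
DS_DNA_G_PER_MOL_PER_BP = 660.0

#: default working concentration for pooled amplicons, ng/uL
DEFAULT_WORKING_CONC = 10.0

#: default minimum pool volume, uL (enough for acoustic shearing)
DEFAULT_MIN_POOL_UL = 130.0

#: smallest per-component volume considered pipettable, uL
DEFAULT_MIN_COMPONENT_UL = 1.0


class PoolingError(ValidationError):
    pass


@dataclass(frozen=True)
class PcrMeasurement:
    """Concentration and product size of one amplicon PCR."""

    amplicon_name: str
    concentration: float  # ng/uL
    size_bp: int

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise PoolingError(f"{self.amplicon_name}: concentration must be > 0")
        if self.size_bp <= 0:
            raise PoolingError(f"{self.amplicon_name}: size_bp must be > 0")


@dataclass(frozen=True)
class LibraryMeasurement:
    """A finalized indexed library: concentration, mean insert, target size."""

    name: str
    concentration: float  # ng/uL
    mean_fragment_bp: int
    target_size_bp: int

    def __post_init__(self) -> None:
        if min(self.concentration, self.mean_fragment_bp, self.target_size_bp) <= 0:
            raise PoolingError(f"{self.name}: all fields must be > 0")


@dataclass
class PoolPlan:
    """Per-component volumes of a pool, plus provenance notes."""

    components: list[tuple[str, float]]
    notes: list[str]

    @property
    def total_volume(self) -> float:
        return round(sum(v for _, v in self.components), 10)

    def volume(self, name: str) -> float:
        for n, v in self.components:
            if n == name:
                return v
        raise KeyError(name)

    def to_tsv(self, handle: TextIO) -> None:
        for note in self.notes:
            handle.write(f"# {note}\n")
        handle.write("name\tvolume_uL\n")
        for name, vol in self.components:
            handle.write(f"{name}\t{vol:.1f}\n")
        handle.write(f"# total_volume_uL\t{self.total_volume:.1f}\n")


def _round_preserving_total(
    names: Sequence[str], volumes: Sequence[float], step: float = 0.1
) -> list[tuple[str, float]]:
    """Round each volume to ``step``, pushing the residue onto the largest
    component so the rounded volumes sum exactly to the rounded total."""
    total = sum(volumes)
    rounded = [round(round(v / step) * step, 10) for v in volumes]
    residue = round(round(total / step) * step - sum(rounded), 10)
    if abs(residue) >= step / 2:
        i_max = max(range(len(volumes)), key=lambda i: volumes[i])
        rounded[i_max] = round(rounded[i_max] + residue, 10)
    return list(zip(names, rounded))


def dilution_plan(
    stock_conc: float, target_conc: float, final_volume: float
) -> tuple[float, float]:
    """Volumes (stock uL, diluent uL) to dilute stock to the target
    concentration at the requested final volume (C1*V1 = C2*V2)."""
    if target_conc <= 0 or final_volume <= 0:
        raise PoolingError("target concentration and final volume must be > 0")
    if stock_conc < target_conc:
        raise PoolingError(
            f"cannot dilute upward: stock {stock_conc} ng/uL below "
            f"target {target_conc} ng/uL"
        )
    stock_vol = target_conc * final_volume / stock_conc
    return stock_vol, final_volume - stock_vol


def amplicon_pool_volumes(
    measurements: Sequence[PcrMeasurement],
    min_total: float = DEFAULT_MIN_POOL_UL,
    working_conc: float = DEFAULT_WORKING_CONC,
    min_component: float = DEFAULT_MIN_COMPONENT_UL,
) -> PoolPlan:
    """Size-proportional pool of amplicons at a common working concentration.

    Each amplicon's volume is proportional to its product size, which makes
    the pool equimolar per template copy: at equal mass concentration, mass
    contributed scales with size, so moles (mass / size) are equal across
    amplicons and every base position is represented equally.

    The pool is scaled to ``min_total`` unless the per-component floor
    (``min_component``) forces a larger total; the note list records which
    regime applied.
    """
    if not measurements:
        raise PoolingError("no amplicon measurements given")
    names = [m.amplicon_name for m in measurements]
    if len(set(names)) != len(names):
        raise PoolingError("duplicate amplicon names in pool")
    sizes = [float(m.size_bp) for m in measurements]
    scale = min_total / sum(sizes)
    volumes = [s * scale for s in sizes]
    notes = [
        f"working_conc_ng_per_uL={working_conc:g}",
        f"min_total_uL={min_total:g}",
        f"scaling=size_proportional factor={scale:.6g} uL/bp",
    ]
    floor_hits = [i for i, v in enumerate(volumes) if v < min_component]
    if floor_hits:
        # raise the whole pool so the smallest component reaches the floor,
        # preserving the size proportions
        boost = min_component / min(volumes)
        volumes = [v * boost for v in volumes]
        notes.append(
            f"per_component_floor_uL={min_component:g} raised total to "
            f"{sum(volumes):.1f} uL ({len(floor_hits)} component(s) below floor)"
        )
    return PoolPlan(_round_preserving_total(names, volumes), notes)


def library_molarity(lib: LibraryMeasurement) -> float:
    """Library molarity in nM from mass concentration and mean fragment size.

    nM = conc[ng/uL] * 1e6 / (660 * mean_fragment_bp); 660 g/mol/bp is the
    standard average molar mass of double-stranded DNA.
    """
    return lib.concentration * 1e6 / (DS_DNA_G_PER_MOL_PER_BP * lib.mean_fragment_bp)


def dilute_library_to(
    lib: LibraryMeasurement, target_nM: float, final_volume: float
) -> tuple[float, float]:
    """(library uL, diluent uL) bringing the library to ``target_nM``."""
    return dilution_plan(library_molarity(lib), target_nM, final_volume)


def index_pool_volumes(
    libs: Sequence[LibraryMeasurement], total_volume: float
) -> PoolPlan:
    """Pool normalized (equal-molarity) libraries proportionally to their
    genomic target sizes, so reads per target base are balanced across
    samples sharing a flow cell."""
    if not libs:
        raise PoolingError("no libraries given")
    total_target = sum(l.target_size_bp for l in libs)
    if total_target <= 0:
        raise PoolingError("zero total target size")
    names = [l.name for l in libs]
    volumes = [total_volume * l.target_size_bp / total_target for l in libs]
    notes = [
        f"total_volume_uL={total_volume:g}",
        "scaling=target_size_proportional (libraries assumed at equal molarity)",
    ]
    return PoolPlan(_round_preserving_total(names, volumes), notes)


def spikein_amount(
    lr_target_bp: int, wes_target_bp: int, wes_library_amount: float
) -> float:
    """Amount of LR library to spike into a whole-exome pool.

    Pure ratio: amount = wes_library_amount * lr_target_bp / wes_target_bp,
    so the spiked-in target receives the same read density as the exome.
    Unit-agnostic (amol, ng, or fractions - whatever the WES amount is in).
    """
    if wes_target_bp <= 0:
        raise PoolingError("WES target size must be > 0")
    if lr_target_bp < 0:
        raise PoolingError("LR target size must be >= 0")
    return wes_library_amount * lr_target_bp / wes_target_bp


# ---------------------------------------------------------------------------
# TSV input


def read_pcr_measurements(handle: TextIO | str) -> list[PcrMeasurement]:
    """Read amplicon measurements from TSV: name, concentration, size_bp."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_pcr_measurements(fh)
    out = []
    for lineno, line in enumerate(handle, 1):
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PoolingError(f"line {lineno}: expected 3 columns")
        out.append(PcrMeasurement(parts[0], float(parts[1]), int(parts[2])))
    return out


def read_library_measurements(handle: TextIO | str) -> list[LibraryMeasurement]:
    """Read library measurements from TSV: name, concentration, fragment_bp,
    target_bp."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_library_measurements(fh)
    out = []
    for lineno, line in enumerate(handle, 1):
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise PoolingError(f"line {lineno}: expected 4 columns")
        out.append(
            LibraryMeasurement(parts[0], float(parts[1]), int(parts[2]), int(parts[3]))
        )
    return out
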