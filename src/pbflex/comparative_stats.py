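"""Comparison statistics between conformational ensembles.

Given per-position PB frequency vectors f = (f_a .. f_p):

* ``Neq = exp(-sum_x f_x ln f_x)`` — the equivalent number of Protein
  Blocks, i.e. the exponential of the Shannon entropy (natural log, with
  0 ln 0 := 0).  Neq is 1 when a single block is ever observed and 16 for
  the uniform distribution over the alphabet.
* ``deltaPB = sum_x |f_x(1) - f_x(2)|`` — the L1 distance between two
  systems' frequency vectors at one position, from 0 (identical PB usage)
  to 2 (disjoint supports).
* ``deltaNeq = |Neq_1 - Neq_2|`` and ``deltaRMSF = RMSF_variant -
  RMSF_wildtype`` (signed) complete the per-position comparison.

These are descriptive statistics; no significance machinery is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_metrics import RmsfVector
from .protein_blocks import PB_LABELS, PBFrequencyProfile
from .structure_io import RegionMap

__all__ = [
    "neq", "neq_profile", "delta_neq", "delta_pb", "delta_rmsf",
    "flexibility_band", "logo_matrix", "FlexibilityProfile",
    "ComparisonTable", "build_flexibility_profile", "compare_systems",
    "PBFrequencyProfile",
]

_NORM_TOL = 1e-6


def _check_normalized(f: np.ndarray, name: str = "frequencies") -> np.ndarray:
    f = np.asarray(f, float)
    if f.shape[-1] != 16:
        raise ValueError(f"{name} must have 16 entries per position")
    if np.any(f < -1e-12):
        raise ValueError(f"{name} contains negative entries")
    sums = f.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _NORM_TOL):
        raise ValueError(f"{name} not normalised (row sums {sums})")
    return np.clip(f, 0.0, 1.0)


def neq(frequencies) -> float:
    """Equivalent number of PBs of one 16-vector of frequencies.

    ``exp(-sum f ln f)`` with natural logarithm and 0 ln 0 := 0; lies in
    [1, 16], attaining 1 iff a single block has all the mass and 16 iff the
    distribution is uniform.
    """
    f = _check_normalized(np.atleast_1d(np.asarray(frequencies, float)))
    nz = f[f > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def neq_profile(profile: PBFrequencyProfile) -> np.ndarray:
    """Per-position Neq of a frequency profile; ``nan`` where unobserved."""
    out = np.full(profile.n_positions, np.nan)
    freqs = profile.frequencies
    for i in np.nonzero(~profile.unobserved)[0]:
        out[i] = neq(freqs[i])
    return out


def delta_neq(neq1: float, neq2: float) -> float:
    """Absolute difference of two Neq values."""
    return float(abs(neq1 - neq2))


def delta_pb(f1, f2) -> float:
    """L1 distance between two normalised 16-vectors of PB frequencies.

    0 means identical PB usage; 2 means disjoint supports.
    """
    a = _check_normalized(np.atleast_1d(np.asarray(f1, float)), "f1")
    b = _check_normalized(np.atleast_1d(np.asarray(f2, float)), "f2")
    return float(np.sum(np.abs(a - b)))


def delta_rmsf(variant: RmsfVector, wildtype: RmsfVector) -> np.ndarray:
    """Signed per-position RMSF difference, variant minus wild type."""
    if list(variant.positions) != list(wildtype.positions):
        raise ValueError("RMSF vectors cover different positions")
    return variant.values - wildtype.values


def flexibility_band(neq_value: float) -> str:
    """Qualitative flexibility label for an Neq value.

    Follows the usual reading of the scale: 1 total rigidity, around 4
    flexible, around 6 highly flexible, 8 or more disordered.
    """
    if not np.isfinite(neq_value):
        return "unobserved"
    if neq_value >= 8:
        return "disordered"
    if neq_value >= 6:
        return "highly flexible"
    if neq_value >= 4:
        return "flexible"
    return "rigid"


def logo_matrix(
    profile: PBFrequencyProfile, start: int, end: int
) -> pd.DataFrame:
    """Positions x 16 frequency slice suitable for any logo renderer.

    ``start`` and ``end`` are inclusive author positions; rows sum to 1 at
    observed positions.
    """
    positions = [p for p in profile.positions if start <= p <= end]
    if not positions:
        raise ValueError(f"no profile positions in range {start}-{end}")
    df = pd.DataFrame(
        profile.frequencies, index=profile.positions, columns=list(PB_LABELS)
    )
    df.index.name = "position"
    return df.loc[positions]


@dataclass
class FlexibilityProfile:
    """Per-position Neq, RMSF and region label for one system."""

    system_label: str
    positions: list[int]
    neq: np.ndarray
    rmsf: np.ndarray
    regions: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "region": self.regions,
            "rmsf": self.rmsf,
            "neq": self.neq,
            "band": [flexibility_band(v) for v in self.neq],
        })


def build_flexibility_profile(
    system_label: str,
    freq_profile: PBFrequencyProfile,
    rmsf_vector: RmsfVector | None,
    region_map: RegionMap,
) -> FlexibilityProfile:
    """Assemble the per-position flexibility profile of one system.

    ``rmsf_vector`` may be None for dihedral-only pipelines, in which case
    the RMSF column is ``nan``.
    """
    positions = list(freq_profile.positions)
    if rmsf_vector is not None and list(rmsf_vector.positions) != positions:
        raise ValueError("RMSF and PB profiles cover different positions")
    rmsf_vals = (
        rmsf_vector.values if rmsf_vector is not None
        else np.full(len(positions), np.nan)
    )
    return FlexibilityProfile(
        system_label=system_label,
        positions=positions,
        neq=neq_profile(freq_profile),
        rmsf=np.asarray(rmsf_vals, float),
        regions=region_map.labels(positions),
    )


@dataclass
class ComparisonTable:
    """Per-position comparison of two systems.

    ``table`` columns: position, region, rmsf1, rmsf2, delta_rmsf, neq1,
    neq2, delta_neq, delta_pb.  Positions where either system is unobserved
    carry ``nan`` (missing), never 0.
    """

    system1_label: str
    system2_label: str
    table: pd.DataFrame

    def region_maxima(self) -> dict:
        """Per-region maxima of deltaPB, deltaNeq and |deltaRMSF|."""
        out = {}
        for region, grp in self.table.groupby("region", sort=False):
            out[str(region)] = {
                "max_delta_pb": _nanmax(grp["delta_pb"]),
                "max_delta_neq": _nanmax(grp["delta_neq"]),
                "max_abs_delta_rmsf": _nanmax(grp["delta_rmsf"].abs()),
            }
        return out


def _nanmax(series: pd.Series):
    vals = series.to_numpy(float)
    return None if np.all(np.isnan(vals)) else float(np.nanmax(vals))


def compare_systems(
    system1: tuple[PBFrequencyProfile, FlexibilityProfile],
    system2: tuple[PBFrequencyProfile, FlexibilityProfile],
    region_map: RegionMap | None = None,
) -> ComparisonTable:
    """Per-position deltaNeq, deltaPB and deltaRMSF between two systems.

    By the sign convention, ``delta_rmsf = system1 - system2`` (pass the
    variant first and the wild type second).  deltaPB and deltaNeq are
    symmetric.  Positions must align exactly between the two systems.
    """
    freq1, flex1 = system1
    freq2, flex2 = system2
    if list(freq1.positions) != list(freq2.positions):
        mis = [
            (a, b) for a, b in zip(freq1.positions, freq2.positions) if a != b
        ]
        raise ValueError(
            f"systems cover different positions; first mismatches: {mis[:5]}"
        )
    positions = list(freq1.positions)
    regions = (
        region_map.labels(positions) if region_map is not None
        else list(flex1.regions)
    )

    f1 = freq1.frequencies
    f2 = freq2.frequencies
    dpb = np.full(len(positions), np.nan)
    ok = ~(freq1.unobserved | freq2.unobserved)
    dpb[ok] = np.sum(np.abs(f1[ok] - f2[ok]), axis=1)

    dneq = np.abs(flex1.neq - flex2.neq)
    drmsf = flex1.rmsf - flex2.rmsf

    table = pd.DataFrame({
        "position": positions,
        "region": regions,
        "rmsf1": flex1.rmsf,
        "rmsf2": flex2.rmsf,
        "delta_rmsf": drmsf,
        "neq1": flex1.neq,
        "neq2": flex2.neq,
        "delta_neq": dneq,
        "delta_pb": dpb,
    })
    return ComparisonTable(
        system1_label=flex1.system_label,
        system2_label=flex2.system_label,
        table=table,
    )
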