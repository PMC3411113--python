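"""Geometric packing metrics over alpha-carbon traces.

The central quantities are sliding-window packing descriptors computed on
a CA trace of N residues:

* distances between CA_i and CA_{i+2} (N-2 values),
* triangle areas and tetrahedron volumes over short CA windows, in two
  variants:

  - ``cog``   — triangles (CA_i, CA_{i+2}, CoG), N-2 values, and
                tetrahedra (CA_i, CA_{i+2}, CA_{i+4}, CoG), N-4 values,
                where CoG is the unweighted centroid of the trace;
  - ``chain`` — triangles (CA_i, CA_{i+2}, CA_{i+3}), N-3 values, and
                tetrahedra (CA_i, CA_{i+2}, CA_{i+3}, CA_{i+4}), N-4
                values, anchored on the chain itself.

Compact, well-packed conformations subtend small areas and volumes
against the centroid; swelling or local unpacking shows up as a rise in
these per-window quantities, which is what the refolding controller
watches.  Both per-window means and sums are reported.

Also here: Kabsch least-squares superposition (proper rotations only) and
CA RMSD, the pairwise ensemble-vs-probe RMSD table, and a whitespace
matrix export of metric series suitable for gnuplot surface plots.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import CATrace, Ensemble, StructureModel, extract_ca_trace

__all__ = [
    "DarvolsProfile",
    "SuperpositionResult",
    "center_of_geometry",
    "triangle_area",
    "tetrahedron_volume",
    "darvols_profile",
    "kabsch_superpose",
    "ensemble_rmsd_table",
    "export_gnuplot_matrix",
    "profile_table",
]

Variant = Literal["cog", "chain"]

MIN_TRACE_FOR_PROFILE = 5


@dataclass
class DarvolsProfile:
    """Per-window packing metrics of one snapshot."""

    variant: str
    distances: np.ndarray  # Å,  N-2 values
    areas: np.ndarray      # Å², N-2 (cog) or N-3 (chain) values
    volumes: np.ndarray    # Å³, N-4 values

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    @property
    def mean_volume(self) -> float:
        return float(np.mean(self.volumes))

    @property
    def sum_area(self) -> float:
        return float(np.sum(self.areas))

    @property
    def sum_volume(self) -> float:
        return float(np.sum(self.volumes))


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: x_ref ≈ rotation @ x_mobile + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _as_points(trace) -> np.ndarray:
    if isinstance(trace, CATrace):
        return trace.coords
    return np.asarray(trace, dtype=float).reshape(-1, 3)


def center_of_geometry(trace) -> np.ndarray:
    """Unweighted centroid of the CA coordinates (Å).

    The trace representation carries no masses, so the "centre of
    gravity" used by the packing metrics is the plain coordinate mean.
    """
    pts = _as_points(trace)
    if len(pts) == 0:
        raise ValueError("centre of geometry of an empty trace is undefined")
    return pts.mean(axis=0)


def triangle_area(p, q, r) -> float:
    """Area of the triangle (p, q, r) in Å²; 0 for collinear points."""
    p, q, r = (np.asarray(x, dtype=float) for x in (p, q, r))
    return 0.5 * float(np.linalg.norm(np.cross(q - p, r - p)))


def tetrahedron_volume(p, q, r, s) -> float:
    """Volume of the tetrahedron (p, q, r, s) in Å³; 0 for coplanar points."""
    p, q, r, s = (np.asarray(x, dtype=float) for x in (p, q, r, s))
    return abs(float(np.dot(q - p, np.cross(r - p, s - p)))) / 6.0


def darvols_profile(trace, variant: Variant = "cog") -> DarvolsProfile:
    """Compute the sliding-window packing profile of a CA trace.

    Parameters
    ----------
    trace:
        CATrace (or (N, 3) array) with N >= 5.
    variant:
        ``"cog"`` anchors triangles/tetrahedra at the trace centroid;
        ``"chain"`` uses only consecutive-window CA atoms.  The two
        definitions probe global versus local packing and are not
        interchangeable, hence the explicit parameter.
    """
    pts = _as_points(trace)
    n = len(pts)
    if n < MIN_TRACE_FOR_PROFILE:
        raise ValueError(
            f"packing profile needs at least {MIN_TRACE_FOR_PROFILE} CA atoms, got {n}"
        )
    if variant not in ("cog", "chain"):
        raise ValueError(f"unknown variant {variant!r}; expected 'cog' or 'chain'")

    distances = np.linalg.norm(pts[2:] - pts[:-2], axis=1)

    if variant == "cog":
        cog = pts.mean(axis=0)
        e1 = pts[:-2] - cog
        e2 = pts[2:] - cog
        areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        a = pts[:-4] - cog
        b = pts[2:-2] - cog
        c = pts[4:] - cog
        volumes = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    else:
        e1 = pts[2:-1] - pts[:-3]
        e2 = pts[3:] - pts[:-3]
        areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        a = pts[2:-2] - pts[:-4]
        b = pts[3:-1] - pts[:-4]
        c = pts[4:] - pts[:-4]
        volumes = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    return DarvolsProfile(variant, distances, areas, volumes)


def kabsch_superpose(mobile, reference) -> SuperpositionResult:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Returns the proper rotation (determinant +1; the reflection branch of
    the underlying SVD is rejected), the translation, and the post-fit CA
    RMSD in Å.
    """
    mob = _as_points(mobile)
    ref = _as_points(reference)
    if len(mob) != len(ref):
        raise ValueError(f"trace lengths differ: {len(mob)} vs {len(ref)}")
    if len(mob) < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd) / np.sqrt(len(mob))
    return SuperpositionResult(R, t, rmsd)


def ca_rmsd(a, b) -> float:
    """Post-superposition CA RMSD between two equal-length traces (Å)."""
    return kabsch_superpose(a, b).rmsd


def ensemble_rmsd_table(ensemble: Ensemble, probe: StructureModel) -> pd.DataFrame:
    """Pairwise CA RMSD of every ensemble member against the ensemble's
    first member ("input") and against a probe structure.

    Returns a DataFrame with columns ``model``, ``rmsd_vs_input``,
    ``rmsd_vs_probe``, ordered by model number.
    """
    traces = [extract_ca_trace(m) for m in ensemble.models]
    probe_trace = extract_ca_trace(probe)
    if len(probe_trace) != len(traces[0]):
        raise ValueError(
            f"probe residue count {len(probe_trace)} does not match ensemble "
            f"residue count {len(traces[0])}"
        )
    rows = []
    for m, tr in zip(ensemble.models, traces):
        rows.append(
            {
                "model": m.model_id,
                "rmsd_vs_input": ca_rmsd(tr, traces[0]),
                "rmsd_vs_probe": ca_rmsd(tr, probe_trace),
            }
        )
    return pd.DataFrame(rows)


def profile_table(profile: DarvolsProfile) -> pd.DataFrame:
    """Per-window TSV-ready table: index, distance, area, volume.

    The three lists have different lengths by construction; shorter
    columns are padded with NaN.
    """
    n = len(profile.distances)
    cols = {
        "window": np.arange(1, n + 1),
        "distance": profile.distances,
        "area": np.full(n, np.nan),
        "volume": np.full(n, np.nan),
    }
    cols["area"][: len(profile.areas)] = profile.areas
    cols["volume"][: len(profile.volumes)] = profile.volumes
    return pd.DataFrame(cols)


def export_gnuplot_matrix(
    series: Sequence[DarvolsProfile],
    which: Literal["area", "volume"],
    sink,
) -> None:
    """Write a metric surface (snapshots x windows) as gnuplot splot text.

    One data block per snapshot, one line per residue window
    (``window  snapshot  value``), blank line between blocks; values keep
    at least 6 significant digits.
    """
    if which not in ("area", "volume"):
        raise ValueError(f"unknown metric {which!r}; expected 'area' or 'volume'")
    if not series:
        raise ValueError("empty profile series")
    variants = {p.variant for p in series}
    attr = "areas" if which == "area" else "volumes"
    lengths = {len(getattr(p, attr)) for p in series}
    if len(variants) > 1 or len(lengths) > 1:
        raise ValueError("profiles in a series must share variant and window count")

    buf = io.StringIO()
    for snap_idx, prof in enumerate(series, start=1):
        for win_idx, value in enumerate(getattr(prof, attr), start=1):
            buf.write(f"{win_idx} {snap_idx} {value:.8g}\n")
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(os.fspath(sink), "w") as fh:
            fh.write(text)
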