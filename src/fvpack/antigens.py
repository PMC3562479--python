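"""Antigen Voronoi volumes, size classification and enrichment statistics.

Antigen size is measured as the summed atomic volume of the bound antigen
under a radical-plane (power) Voronoi partition: each atom owns the region
of space closer to it (in power distance, which accounts for differing
atomic radii) than to any other atom, and unbounded surface cells are
capped by the atom's solvent-extended sphere (van der Waals radius plus a
1.4 Å probe).  Cell volumes are computed exactly: the power cell is built
as a half-space intersection and its intersection with the capping sphere
is evaluated in closed form face by face (planar piece + spherical
sector), so volumes are invariant under rigid motion to machine precision.

Small antigens (haptens) are separated from peptide/protein antigens by a
volume threshold; over-representation of small-antigen binders inside one
packing-mode cluster is scored with the exact upper-tail hypergeometric
probability, and continuous distance distributions are compared between
clusters with a binned Pearson chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from math import comb
from typing import Sequence

import numpy as np
from scipy.spatial import HalfspaceIntersection
from scipy.stats import chi2

from .model import FvError

PROBE_RADIUS = 1.4  # Å, water probe used to cap surface cells
DEFAULT_RADIUS = 1.7  # Å, fallback for unknown elements
SMALL_ANTIGEN_THRESHOLD = 505.0  # Å³, hapten vs peptide/protein boundary


def _load_radii() -> dict[str, float]:
    table = {}
    text = resources.files("fvpack").joinpath("data/bondi_radii.tsv").read_text()
    for line in text.strip().splitlines()[1:]:
        el, r = line.split("\t")
        table[el.upper()] = float(r)
    return table


BONDI_RADII = _load_radii()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for an element symbol (Å)."""
    el = element.strip().upper()
    if el not in BONDI_RADII:
        warnings.warn(f"unknown element {element!r}; using {DEFAULT_RADIUS} Å", stacklevel=2)
        return DEFAULT_RADIUS
    return BONDI_RADII[el]


@dataclass
class AntigenRecord:
    structure_id: str
    n_atoms: int
    volume: float
    size_class: str  # small | large


@dataclass
class EnrichmentTable:
    """Hypergeometric enrichment of small-antigen binders in one cluster."""

    N: int  # total bound antibodies
    K: int  # small-antigen binders overall
    n: int  # bound antibodies in the tested cluster
    k: int  # small-antigen binders inside the cluster
    p: float  # upper-tail probability P(X >= k)


# ---------------------------------------------------------------------------
# Exact sphere-polyhedron geometry


def _signed_triangle_solid_angle(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray) -> float:
    """Signed solid angle of a triangle seen from the origin (Van Oosterom)."""
    n1, n2, n3 = np.linalg.norm(r1), np.linalg.norm(r2), np.linalg.norm(r3)
    num = float(np.dot(r1, np.cross(r2, r3)))
    den = n1 * n2 * n3 + np.dot(r1, r2) * n3 + np.dot(r2, r3) * n1 + np.dot(r3, r1) * n2
    return 2.0 * float(np.arctan2(num, den))


def _face_pieces(poly2d: np.ndarray, rho: float):
    """Decompose the boundary of (polygon ∩ disk of radius rho, both centred
    at the 2D origin) into straight chords and circular-arc sectors.

    Yields ("tri", a, b) for straight pieces and ("arc", u, v) for arc
    pieces, where the arc runs from direction u to direction v (each
    subtending < pi).  Signed Green's-theorem decomposition: valid for any
    polygon, any origin location.
    """
    m = len(poly2d)
    rho2 = rho * rho
    for i in range(m):
        p = poly2d[i]
        q = poly2d[(i + 1) % m]
        dp = q - p
        a_ = float(np.dot(dp, dp))
        if a_ == 0.0:
            continue
        b_ = 2.0 * float(np.dot(p, dp))
        c_ = float(np.dot(p, p)) - rho2
        disc = b_ * b_ - 4.0 * a_ * c_
        ts: list[float] = []
        if disc > 0:
            sq = np.sqrt(disc)
            ts = sorted(((-b_ - sq) / (2 * a_), (-b_ + sq) / (2 * a_)))
        p_in = c_ <= 0
        q_in = float(np.dot(q, q)) - rho2 <= 0
        if p_in and q_in:
            yield ("tri", p, q)
        elif disc <= 0 or ts[1] <= 0 or ts[0] >= 1:
            # edge entirely outside the disk: pure arc from p-dir to q-dir
            yield ("arc", p, q)
        else:
            t0, t1 = max(ts[0], 0.0), min(ts[1], 1.0)
            a_pt = p + t0 * dp
            b_pt = p + t1 * dp
            if t0 > 0:
                yield ("arc", p, a_pt)
            yield ("tri", a_pt, b_pt)
            if t1 < 1:
                yield ("arc", b_pt, q)


def _clipped_face_volume(verts3d: np.ndarray, normal: np.ndarray, center: np.ndarray, R: float) -> float:
    """Exact contribution of one outward-oriented polyhedron face to the
    volume of (polyhedron ∩ ball of radius R centred at ``center``).

    Contribution = (h/3)·Area(F ∩ D) + (R³/3)·(Ω(F) − Ω(F ∩ D)), where h
    is the signed plane distance, D the cap disk and Ω solid angles from
    the ball centre.
    """
    h = float(np.dot(verts3d[0] - center, normal))
    foot = center + h * normal
    # 2D frame in the face plane (right-handed with the outward normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    # (e1, e2, normal) right-handed => CCW in (e1,e2) is outward orientation
    if np.dot(np.cross(e1, e2), normal) < 0:
        e2 = -e2
    poly2d = np.array([[np.dot(v - foot, e1), np.dot(v - foot, e2)] for v in verts3d])

    # full-face solid angle from the centre (fan from the foot point)
    omega_full = 0.0
    m = len(poly2d)
    hv = np.array([0.0, 0.0, h])  # foot point in local frame, seen from centre

    def lift(u2d):
        return np.array([u2d[0], u2d[1], h])

    for i in range(m):
        omega_full += _signed_triangle_solid_angle(hv, lift(poly2d[i]), lift(poly2d[(i + 1) % m]))

    if h >= R:
        # plane beyond the ball: pure spherical sector
        return (R**3 / 3.0) * omega_full
    rho = float(np.sqrt(max(R * R - h * h, 0.0)))

    area_clip = 0.0
    omega_clip = 0.0
    sector_omega = 1.0 - h / R
    for kind, u, v in _face_pieces(poly2d, rho):
        if kind == "tri":
            area_clip += 0.5 * float(u[0] * v[1] - u[1] * v[0])
            omega_clip += _signed_triangle_solid_angle(hv, lift(u), lift(v))
        else:
            dth = float(np.arctan2(u[0] * v[1] - u[1] * v[0], np.dot(u, v)))
            area_clip += 0.5 * rho * rho * dth
            omega_clip += dth * sector_omega
    return (h / 3.0) * area_clip + (R**3 / 3.0) * (omega_full - omega_clip)


def _power_cell_volume(
    center: np.ndarray,
    radius: float,
    others: Sequence[tuple[np.ndarray, float]],
    probe: float,
) -> float:
    """Volume of one atom's power cell clipped to its solvent sphere."""
    R = radius + probe
    halfspaces = []  # rows [a, b, c, d] meaning ax+by+cz+d <= 0
    for xj, rj in others:
        delta = xj - center
        dist = float(np.linalg.norm(delta))
        if dist < 1e-9:
            raise FvError("coincident atom centers")
        u = delta / dist
        h = (dist * dist + radius * radius - rj * rj) / (2.0 * dist)
        if h <= 1e-9:
            raise FvError("atom center lies outside its own power cell (strongly overlapping atoms)")
        if h >= R:
            continue
        halfspaces.append([*u, -(float(np.dot(u, center)) + h)])
    if not halfspaces:
        return (4.0 / 3.0) * np.pi * R**3
    # bounding cube keeps the polyhedron finite; its faces lie beyond the ball
    box = R + 1.0
    for axis in range(3):
        for sign in (1.0, -1.0):
            u = np.zeros(3)
            u[axis] = sign
            halfspaces.append([*u, -(float(np.dot(u, center)) + box)])
    hs = HalfspaceIntersection(np.array(halfspaces), interior_point=center.astype(float))
    verts = hs.intersections
    A = np.array(halfspaces)
    vol = 0.0
    scale = max(1.0, float(np.abs(verts).max()))
    for row in A:
        normal, d = row[:3], row[3]
        on = np.abs(verts @ normal + d) < 1e-8 * scale
        face = verts[on]
        if len(face) < 3:
            continue
        # deduplicate and order vertices around the face centroid
        fc = face.mean(axis=0)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(normal, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        if np.dot(np.cross(e1, e2), normal) < 0:
            e2 = -e2
        ang = np.arctan2((face - fc) @ e2, (face - fc) @ e1)
        order = np.argsort(ang)
        face = face[order]
        keep = [0]
        for i in range(1, len(face)):
            if np.linalg.norm(face[i] - face[keep[-1]]) > 1e-9 * scale:
                keep.append(i)
        if len(keep) >= 3 and np.linalg.norm(face[keep[0]] - face[keep[-1]]) <= 1e-9 * scale:
            keep = keep[:-1]
        if len(keep) < 3:
            continue
        vol += _clipped_face_volume(face[keep], normal, center, R)
    return float(vol)


def voronoi_volume(
    atoms: Sequence[tuple[str, np.ndarray, float]],
    context_atoms: Sequence[tuple[str, np.ndarray, float]] = (),
    probe: float = PROBE_RADIUS,
) -> float:
    """Summed radical-plane Voronoi volume of an atom set (Å³).

    ``atoms`` are (element, xyz, vdw_radius) triples whose cell volumes are
    summed; ``context_atoms`` (e.g. antibody atoms surrounding the bound
    antigen) bound the cells but contribute no volume.  Surface cells are
    capped by each atom's vdW + probe sphere.
    """
    if len(atoms) == 0:
        raise FvError("at least one atom required")
    sites = [(np.asarray(xyz, dtype=float), float(r)) for _, xyz, r in atoms]
    ctx = [(np.asarray(xyz, dtype=float), float(r)) for _, xyz, r in context_atoms]
    total = 0.0
    for i, (xi, ri) in enumerate(sites):
        others = [s for j, s in enumerate(sites) if j != i] + ctx
        total += _power_cell_volume(xi, ri, others, probe)
    return total


# ---------------------------------------------------------------------------
# Size classification


def quartile_threshold(volumes: Sequence[float]) -> float:
    """First quartile of a volume sample (linear interpolation)."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise FvError("empty volume sample")
    return float(np.percentile(v, 25))


def classify_antigen_size(volume: float, threshold: float = SMALL_ANTIGEN_THRESHOLD) -> str:
    """``small`` iff volume is strictly below the threshold, else ``large``."""
    return "small" if volume < threshold else "large"


# ---------------------------------------------------------------------------
# Statistics


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) of Hypergeometric(N, K, n).

    Probability of drawing at least ``k`` small-antigen binders when ``n``
    antibodies are sampled without replacement from ``N`` of which ``K``
    bind small antigens.  Computed in exact integer arithmetic.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise FvError(f"infeasible counts N={N} K={K} n={n} k={k}")
    if k > min(K, n):
        raise FvError(f"k={k} exceeds min(K={K}, n={n})")
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(num, comb(N, n)))


def enrichment_table(
    cluster_bound: Sequence[bool], cluster_small: Sequence[bool], tested_cluster
) -> EnrichmentTable:
    """Build the enrichment table for one cluster from per-structure flags.

    ``cluster_bound``: cluster label per bound antibody; ``cluster_small``:
    whether each bound antibody's antigen is small.  Tests whether the
    given cluster holds at least as many small-antigen binders as expected.
    """
    labels = list(cluster_bound)
    small = list(cluster_small)
    if len(labels) != len(small):
        raise FvError("label and size-class lists differ in length")
    N = len(labels)
    K = sum(small)
    n = sum(1 for lab in labels if lab == tested_cluster)
    k = sum(1 for lab, s in zip(labels, small) if lab == tested_cluster and s)
    return EnrichmentTable(N, K, n, k, hypergeometric_tail(N, K, n, k))


def chi_squared_two_sample(
    x: Sequence[float], y: Sequence[float], bins: int = 8
) -> tuple[float, float]:
    """Pearson chi-squared comparison of two continuous samples.

    Both samples are histogrammed on equal-width bins over the pooled
    range; adjacent bins are merged until every expected count is >= 5;
    the Pearson statistic on the resulting 2 x B table is referred to a
    chi-squared distribution with B - 1 degrees of freedom.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise FvError("both samples must be non-empty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    ox, _ = np.histogram(x, bins=edges)
    oy, _ = np.histogram(y, bins=edges)
    obs = np.vstack([ox, oy]).astype(float)

    def expected(o: np.ndarray) -> np.ndarray:
        rowsum = o.sum(axis=1, keepdims=True)
        colsum = o.sum(axis=0, keepdims=True)
        return rowsum * colsum / o.sum()

    while obs.shape[1] >= 2:
        e = expected(obs)
        bad = np.nonzero(e.min(axis=0) < 5)[0]
        if bad.size == 0:
            break
        j = int(bad[0])
        partner = j + 1 if j + 1 < obs.shape[1] else j - 1
        lo_, hi_ = min(j, partner), max(j, partner)
        merged = obs[:, lo_] + obs[:, hi_]
        obs = np.delete(obs, hi_, axis=1)
        obs[:, lo_] = merged
    B = obs.shape[1]
    if B < 2:
        raise FvError("insufficient spread: fewer than 2 bins after merging")
    e = expected(obs)
    stat = float(((obs - e) ** 2 / e).sum())
    p = float(chi2.sf(stat, B - 1))
    return stat, p
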