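"""Synthetic Fv-like structures with two planted VH–VL packing modes.

The generator emulates the statistical structure the analysis assumes,
without requiring any structure downloads:

* two packing modes, A and B, realised as two coordinate templates that
  share the heavy-chain block while the light-chain block of B is rotated
  and translated relative to A;
* mode-dependent Gaussian distributions of the three diagnostic Cα
  distances — L36–H100X (A: 9.79 ± 1.36 Å, B: 8.22 ± 1.17 Å),
  L55–H57 (A: 26.49 ± 0.98, B: 24.82 ± 1.39) and
  L24–H25 (A: 35.87 ± 0.65, B: 34.95 ± 0.58);
* mode-linked residue composition at L36, L44 and H100X (type A always
  carries proline at L44) plus secondary profiles at L41–L43, L8, L28 and
  L66;
* bound antigens with a bimodal volume distribution straddling the 505 Å³
  hapten threshold, attached so that small antigens concentrate on mode B
  (defaults: 14 of 25 bound-B vs 3 of 46 bound-A small).

Each structure is drawn from a named random substream keyed by the dataset
seed and the structure index, so adding a structure never perturbs the
others, and the full dataset is byte-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .antigens import voronoi_volume, vdw_radius
from .model import FvStructure, NumberedSequence, PositionId

_pp = PositionId.parse

# positions carried by the synthetic scaffold (only those the analysis touches)
LIGHT_POSITIONS = tuple(
    _pp(p)
    for p in "L8 L24 L28 L34 L36 L38 L41 L42 L43 L44 L46 L55 L66 L87 L89 L98 L100".split()
)
HEAVY_POSITIONS = tuple(
    _pp(p)
    for p in "H25 H35 H37 H39 H44 H45 H47 H57 H91 H93 H96 H97 H98 H100 H100A H100B H101 H103 H105".split()
)

# hypervariable CDR-H3 stand-ins: drawn uniformly in both modes, so every
# structure carries an essentially unique V-region (as real antibodies do)
# and they act as pure-noise features for the position-importance ranking
DIVERSE_POSITIONS = ("H96", "H97", "H98")
_DIVERSE_ALPHABET = "ADEFGHIKLMNPQRSTVY"
H100X = _pp("H100B")  # the last insertion before H101 in this scaffold

# diagnostic distance targets (mean, sd) per mode, Å
DISTANCE_TARGETS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("L36", "H100B"): {"A": (9.79, 1.36), "B": (8.22, 1.17)},
    ("L55", "H57"): {"A": (26.49, 0.98), "B": (24.82, 1.39)},
    ("L24", "H25"): {"A": (35.87, 0.65), "B": (34.95, 0.58)},
}

# residue profiles per mode; L36/L44/H100X frequencies follow the observed
# cluster compositions, the remaining discriminative positions are
# configurable stand-ins with the same flavour (B-conserved L8/L28/L66)
SEQUENCE_PROFILES: dict[str, dict[str, dict[str, float]]] = {
    "L36": {
        "A": {"Y": 58 / 69, "F": 8 / 69, "L": 2 / 69, "N": 1 / 69},
        "B": {"V": 22 / 31, "Y": 5 / 31, "L": 2 / 31, "F": 1 / 31, "I": 1 / 31},
    },
    "L44": {
        "A": {"P": 1.0},
        "B": {"F": 24 / 31, "V": 5 / 31, "I": 2 / 31},
    },
    "H100B": {
        "A": {
            "F": 28 / 69, "M": 21 / 69, "V": 5 / 69, "S": 4 / 69,
            "P": 4 / 69, "G": 3 / 69, "L": 3 / 69, "I": 1 / 69,
        },
        "B": {"F": 14 / 31, "M": 7 / 31, "G": 5 / 31, "L": 4 / 31, "S": 1 / 31},
    },
    "L41": {"A": {"G": 0.85, "A": 0.15}, "B": {"D": 0.8, "G": 0.2}},
    "L42": {"A": {"Q": 0.8, "K": 0.2}, "B": {"S": 0.85, "A": 0.15}},
    "L43": {"A": {"S": 0.7, "A": 0.3}, "B": {"P": 0.8, "S": 0.2}},
    "L8": {"A": {"P": 0.9, "S": 0.1}, "B": {"S": 1.0}},
    "L28": {"A": {"S": 0.6, "N": 0.4}, "B": {"A": 1.0}},
    "L66": {"A": {"G": 0.9, "S": 0.1}, "B": {"K": 1.0}},
}

# invariant framework residues (identical distribution in both modes)
_CONSERVED = {
    "L34": "A", "L38": "Q", "L46": "L", "L87": "Y", "L89": "Q",
    "L98": "F", "L100": "Q", "L24": "R", "L55": "E",
    "H35": "W", "H37": "V", "H39": "Q", "H44": "G", "H45": "L",
    "H47": "W", "H91": "Y", "H93": "A", "H103": "W", "H105": "Q",
    "H25": "S", "H57": "T", "H100": "G", "H100A": "D", "H101": "D",
    "H96": "G", "H97": "S", "H98": "Y",  # template values; randomised per sample
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic dataset (defaults: published counts)."""

    n_A_bound: int = 46
    n_A_unbound: int = 23
    n_B_bound: int = 25
    n_B_unbound: int = 6
    n_A_small: int = 3  # bound mode-A antibodies with a small antigen
    n_B_small: int = 14
    sigma: float = 0.3  # Å, isotropic coordinate jitter
    small_volume_mean: float = 450.0  # Å³
    large_volume_mean: float = 900.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_A_small > self.n_A_bound or self.n_B_small > self.n_B_bound:
            raise ValueError("small-antigen counts exceed bound counts")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _base_coordinates() -> dict[PositionId, np.ndarray]:
    """Deterministic scaffold coordinates shared by both templates.

    Light block centred near x = -7, heavy near x = +7; binding-site
    anchor atoms (L24/L55/H25/H57) sit at the domain periphery.  Exact
    diagnostic distances are imposed afterwards by snapping the light
    anchor of each pair along the pair axis.
    """
    rng = np.random.default_rng(20110821)
    coords: dict[PositionId, np.ndarray] = {}
    anchors = {
        "L24": (-13.0, -13.5, 2.5),
        "L55": (-10.0, 10.5, -1.5),
        "H25": (12.5, 14.0, -3.0),
        "H57": (10.5, -11.0, 2.0),
    }
    for name, xyz in anchors.items():
        coords[_pp(name)] = np.array(xyz)

    def fill(positions, center):
        placed = [coords[p] for p in coords]
        for pos in positions:
            if pos in coords:
                continue
            for _ in range(1000):
                cand = center + rng.uniform(-6.5, 6.5, size=3)
                if all(np.linalg.norm(cand - q) >= 3.4 for q in placed):
                    break
            coords[pos] = cand
            placed.append(cand)

    fill(LIGHT_POSITIONS, np.array([-7.0, 0.0, 0.0]))
    fill(HEAVY_POSITIONS, np.array([7.0, 0.0, 0.0]))
    # L43-L44 must be a bonded neighbour pair (3.80 Å, trans CA-CA)
    l43, l44 = _pp("L43"), _pp("L44")
    coords[l44] = coords[l43] + 3.80 * _unit(coords[l44] - coords[l43])
    return coords


# rotation of the light block that realises the mode-B packing; frozen
# design-time calibration giving a template separation 1 - GDT_HA well
# above the 0.1 floor while keeping both templates Fv-like
_B_ANGLE_DEG = 24.0
_B_SHIFT = np.array([0.9, 0.6, -0.4])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _snap_distances(coords: dict[PositionId, np.ndarray], mode: str) -> None:
    """Move the light anchor of each diagnostic pair along the pair axis so
    the Cα distance equals the mode mean exactly."""
    for (lname, hname), modes in DISTANCE_TARGETS.items():
        mean, _ = modes[mode]
        lp, hp = _pp(lname), _pp(hname)
        axis = _unit(coords[lp] - coords[hp])
        coords[lp] = coords[hp] + mean * axis


def _template_coords(mode: str) -> dict[PositionId, np.ndarray]:
    coords = {p: v.copy() for p, v in _base_coordinates().items()}
    if mode == "B":
        light = [p for p in coords if p.chain == "L"]
        centroid = np.mean([coords[p] for p in light], axis=0)
        R = _rot_z(_B_ANGLE_DEG)
        for p in light:
            coords[p] = R @ (coords[p] - centroid) + centroid + _B_SHIFT
    elif mode != "A":
        raise ValueError(f"mode must be 'A' or 'B', got {mode!r}")
    _snap_distances(coords, mode)
    return coords


def _modal_sequences(mode: str) -> dict[str, NumberedSequence]:
    light, heavy = {}, {}
    for pos in LIGHT_POSITIONS + HEAVY_POSITIONS:
        name = pos.render()
        if name in SEQUENCE_PROFILES:
            profile = SEQUENCE_PROFILES[name][mode]
            res = max(sorted(profile), key=lambda r: profile[r])
        else:
            res = _CONSERVED[name]
        (light if pos.chain == "L" else heavy)[pos] = res
    return {"L": NumberedSequence(light), "H": NumberedSequence(heavy)}


# ideal peptide-unit geometry for the L43-L44 backbone (DD: only this pair
# carries N/C atoms; enough to evaluate the omega dihedral)
_CA_C = 1.52
_C_N = 1.33
_N_CA = 1.46


def _canonical_peptide(omega_deg: float) -> np.ndarray:
    """CA(i-1), C(i-1), N(i), CA(i) with the requested omega dihedral."""
    ca1 = np.zeros(3)
    c = np.array([_CA_C, 0.0, 0.0])
    ang = np.radians(180.0 - 116.0)
    n = c + _C_N * np.array([np.cos(ang), np.sin(ang), 0.0])
    # place CA(i) at angle C-N-CA = 122 deg with dihedral omega about C->N
    u = _unit(n - c)
    ref = np.array([0.0, 0.0, 1.0])
    v = _unit(np.cross(ref, u))
    w = np.cross(u, v)
    theta = np.radians(180.0 - 122.0)
    om = np.radians(omega_deg)
    direction = np.cos(theta) * u + np.sin(theta) * (np.cos(om) * _in_plane(v, w, ca1, c, n) + np.sin(om) * _out_plane(v, w, ca1, c, n))
    ca2 = n + _N_CA * direction
    return np.vstack([ca1, c, n, ca2])


def _in_plane(v, w, ca1, c, n):
    # component in the CA1-C-N plane, pointing back toward CA1's side
    u = _unit(n - c)
    back = ca1 - n
    back = back - np.dot(back, u) * u
    return _unit(back)


def _out_plane(v, w, ca1, c, n):
    u = _unit(n - c)
    return _unit(np.cross(u, _in_plane(v, w, ca1, c, n)))


def _place_backbone(ca_prev: np.ndarray, ca_next: np.ndarray, omega_deg: float) -> dict[str, np.ndarray]:
    """Rigidly place the canonical peptide so its CA pair lands on the two
    given Cα positions (the inter-CA distance is snapped beforehand)."""
    quad = _canonical_peptide(omega_deg)
    d0 = np.linalg.norm(quad[3] - quad[0])
    ca_next = ca_prev + d0 * _unit(ca_next - ca_prev)

    def frame(a, b):
        x = _unit(b - a)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, x)) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        z = _unit(np.cross(x, ref))
        y = np.cross(z, x)
        return np.column_stack([x, y, z])

    F0 = frame(quad[0], quad[3])
    F1 = frame(ca_prev, ca_next)
    R = F1 @ F0.T
    placed = (quad - quad[0]) @ R.T + ca_prev
    return {
        "prev_CA": placed[0], "prev_C": placed[1],
        "N": placed[2], "CA": placed[3],
    }


def make_mode_template(mode: str) -> FvStructure:
    """Deterministic noise-free scaffold realising one packing mode."""
    coords = _template_coords(mode)
    seqs = _modal_sequences(mode)
    s = FvStructure(
        id=f"template_{mode}",
        light_type="kappa" if mode == "A" else "lambda",
        species="synthetic",
        resolution=1.0,
        sequences=seqs,
        ca_coords=coords,
    )
    _attach_backbone(s, omega_deg=180.0)
    return s


def _attach_backbone(s: FvStructure, omega_deg: float) -> None:
    l43, l44 = _pp("L43"), _pp("L44")
    atoms = _place_backbone(s.ca_coords[l43], s.ca_coords[l44], omega_deg)
    s.ca_coords[l44] = atoms["CA"]
    s.backbone[l43] = {"CA": atoms["prev_CA"], "C": atoms["prev_C"]}
    s.backbone[l44] = {"N": atoms["N"], "CA": atoms["CA"]}


def _draw_profile(profile: dict[str, float], rng: np.random.Generator) -> str:
    residues = sorted(profile)
    probs = np.array([profile[r] for r in residues])
    return residues[int(rng.choice(len(residues), p=probs / probs.sum()))]


def sample_structure(
    spec: SyntheticSpec,
    mode: str,
    rng: np.random.Generator,
    structure_id: str = "syn",
    cis_l44: bool = False,
) -> FvStructure:
    """One random Fv of the given mode.

    Coordinates are the mode template plus isotropic Gaussian jitter of
    ``spec.sigma``; the three diagnostic distances are then imposed
    exactly by re-placing the light anchor along the (jittered) pair axis
    at a distance drawn from the mode's Gaussian, so each distance is
    exactly Gaussian with the target mean and sd.  Sequences are drawn
    from the mode profiles; mode A always carries proline at L44.
    """
    template = _template_coords(mode)
    coords = {p: v + rng.normal(0.0, spec.sigma, size=3) for p, v in template.items()}
    for (lname, hname), modes in DISTANCE_TARGETS.items():
        mean, sd = modes[mode]
        target = rng.normal(mean, sd)
        lp, hp = _pp(lname), _pp(hname)
        coords[lp] = coords[hp] + abs(target) * _unit(coords[lp] - coords[hp])

    light, heavy = {}, {}
    for pos in LIGHT_POSITIONS + HEAVY_POSITIONS:
        name = pos.render()
        if name in SEQUENCE_PROFILES:
            res = _draw_profile(SEQUENCE_PROFILES[name][mode], rng)
        elif name in DIVERSE_POSITIONS:
            res = _DIVERSE_ALPHABET[int(rng.integers(len(_DIVERSE_ALPHABET)))]
        else:
            res = _CONSERVED[name]
        (light if pos.chain == "L" else heavy)[pos] = res

    light_type = "lambda" if (mode == "B" and rng.random() < 23 / 31) else (
        "lambda" if mode == "A" and rng.random() < 21 / 69 else "kappa"
    )
    s = FvStructure(
        id=structure_id,
        light_type=light_type,
        species="Mus musculus" if mode == "B" else ("Homo sapiens" if rng.random() < 0.4 else "Mus musculus"),
        resolution=round(float(rng.uniform(1.5, 2.9)), 2),
        sequences={"L": NumberedSequence(light), "H": NumberedSequence(heavy)},
        ca_coords=coords,
    )
    _attach_backbone(s, omega_deg=0.0 if cis_l44 else 180.0)
    return s


def sample_antigen(
    spec: SyntheticSpec, size_class: str, rng: np.random.Generator
) -> list[tuple[str, np.ndarray, float]]:
    """Random close-packed atom blob with a Voronoi volume in the class.

    Atoms are added one by one near existing atoms until the target volume
    (small: ~``small_volume_mean``, capped strictly below 505 Å³; large:
    ~``large_volume_mean``) is reached.
    """
    if size_class not in ("small", "large"):
        raise ValueError(f"size_class must be small/large, got {size_class!r}")
    if size_class == "small":
        target = float(np.clip(rng.normal(spec.small_volume_mean, 20.0), 360.0, 495.0))
    else:
        target = max(float(rng.normal(spec.large_volume_mean, 60.0)), 600.0)
    elements = ["C", "N", "O"]
    atoms: list[tuple[str, np.ndarray, float]] = []
    center = np.array([0.0, 18.0, 0.0])  # sits above the binding site

    def add_atom():
        el = elements[int(rng.choice(3, p=[0.7, 0.15, 0.15]))]
        for _ in range(200):
            if not atoms:
                pos = center + rng.normal(0, 0.5, size=3)
            else:
                base = atoms[int(rng.integers(len(atoms)))][1]
                direction = rng.normal(size=3)
                pos = base + rng.uniform(2.7, 3.2) * direction / np.linalg.norm(direction)
            if all(np.linalg.norm(pos - a[1]) >= 2.5 for a in atoms):
                atoms.append((el, pos, vdw_radius(el)))
                return

    add_atom()
    while voronoi_volume(atoms) < target:
        add_atom()
    if size_class == "small":
        while len(atoms) > 1 and voronoi_volume(atoms) >= 505.0:
            atoms.pop()
    return atoms


def generate_dataset(spec: Optional[SyntheticSpec] = None) -> tuple[list[FvStructure], pd.DataFrame]:
    """Full synthetic dataset plus the hidden ground-truth table.

    Returns the structures and a truth DataFrame with one row per
    structure: id, mode, bound, antigen_class (small/large/none).  Small
    antigens are attached preferentially to mode B, reproducing the
    published enrichment counts under the default spec.
    """
    spec = spec or SyntheticSpec()
    plan: list[tuple[str, bool, Optional[str]]] = []
    for i in range(spec.n_A_bound):
        plan.append(("A", True, "small" if i < spec.n_A_small else "large"))
    for _ in range(spec.n_A_unbound):
        plan.append(("A", False, None))
    for i in range(spec.n_B_bound):
        plan.append(("B", True, "small" if i < spec.n_B_small else "large"))
    for _ in range(spec.n_B_unbound):
        plan.append(("B", False, None))

    # deterministic shuffle of attachment order so small/large binders are
    # not clustered by index
    order_rng = np.random.default_rng([spec.seed, 0xA11])
    order = order_rng.permutation(len(plan))

    structures = []
    rows = []
    for new_idx, plan_idx in enumerate(order):
        mode, bound, ag_class = plan[int(plan_idx)]
        sid = f"syn{new_idx:03d}"
        rng = np.random.default_rng([spec.seed, new_idx])
        s = sample_structure(spec, mode, rng, structure_id=sid)
        if bound:
            s.antigen = sample_antigen(spec, ag_class, rng)
        structures.append(s)
        rows.append(
            {"id": sid, "mode": mode, "bound": bound, "antigen_class": ag_class or "none"}
        )
    return structures, pd.DataFrame(rows)
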