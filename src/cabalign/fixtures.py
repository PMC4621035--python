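"""Synthetic polypeptide fixtures with realistic heavy-atom geometry.

Generates poly-alanine chains (N, CA, C, O, CB per residue) on ideal
secondary-structure CA traces: ideal alpha-helices (1.5 Å rise, 100 deg per
residue), extended strands, and two-domain hinge pairs — two helical domains
joined by an extended linker, with the second conformer's distal domain
rigidly rotated about a pivot residue in the linker.  The hinge pair
emulates an open/closed domain rearrangement: the two conformers have
near-identical residue-residue contact-area matrices but grossly different
global shapes, which is exactly the regime a contact-based aligner must
handle and a superposition-based one cannot.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import DEFAULT_RADIUS, VDW_RADII
from .structure import AtomRecord, ChainStructure, ResidueRecord

HELIX_RADIUS = 2.28      # Å; gives CA-CA = 3.80 with the rise/twist below
HELIX_RISE = 1.5         # Å per residue
HELIX_TWIST = 100.0      # degrees per residue
EXTENDED_STEP = 3.33     # Å along the strand axis
EXTENDED_ZIGZAG = 0.90   # Å lateral alternation

#: Minimum inter-domain heavy-atom distance (Å) guaranteeing that the two
#: domains of a hinge pair share no surface contact at the default surface
#: parameters: c * (r_max + r_max) + cutoff = 1.5 * 3.6 + 2.8 = 8.2.
MIN_DOMAIN_SEPARATION = 8.5

_MIN_RESIDUES = 7


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure (or hinge pair)."""

    n_residues: int = 30
    geometry: str = "ideal_helix"   # ideal_helix | extended | two_domain
    hinge_angle: float = 90.0       # degrees, two_domain only
    linker_length: int = 6
    seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.n_residues < _MIN_RESIDUES:
            raise ValueError(f"need at least {_MIN_RESIDUES} residues")
        if not 0.0 <= self.hinge_angle <= 180.0:
            raise ValueError("hinge angle must be in [0, 180] degrees")


def _helix_trace(n: int) -> np.ndarray:
    phi = np.deg2rad(HELIX_TWIST) * np.arange(n)
    return np.column_stack([HELIX_RADIUS * np.cos(phi),
                            HELIX_RADIUS * np.sin(phi),
                            HELIX_RISE * np.arange(n)])


def _extended_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([EXTENDED_STEP * i,
                            EXTENDED_ZIGZAG * (-1.0) ** i,
                            np.zeros(n)])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    e = np.array([1.0, 0.0, 0.0])
    if abs(v @ e) > 0.9 * np.linalg.norm(v):
        e = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, e))


def _decorate(ca: np.ndarray) -> list[list[tuple[str, str, np.ndarray]]]:
    """Place N, C, O, CB around each CA from local chain frames.

    Bond lengths are realistic (N-CA 1.46, CA-C 1.52, C=O 1.23, CA-CB 1.53 Å)
    and directions follow the local tangent/curvature frame, which is all
    the surface model needs; exact dihedral stereochemistry is not modelled.
    """
    n = len(ca)
    residues = []
    for i in range(n):
        u_prev = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[1] - ca[0])
        u_next = _unit(ca[i + 1] - ca[i]) if i < n - 1 else _unit(ca[-1] - ca[-2])
        tangent = _unit(u_prev + u_next)
        bend = u_next - u_prev
        if np.linalg.norm(bend) > 1e-6:
            outward = -_unit(bend - (bend @ tangent) * tangent) \
                if np.linalg.norm(bend - (bend @ tangent) * tangent) > 1e-6 \
                else _perp(tangent)
        else:
            outward = _perp(tangent)
        binorm = _unit(np.cross(tangent, outward))
        atoms = [
            ("N", "N", ca[i] + 1.46 * _unit(-u_prev + 0.45 * outward)),
            ("CA", "C", ca[i].copy()),
            ("C", "C", ca[i] + 1.52 * _unit(u_next + 0.45 * outward)),
            ("O", "O", ca[i] + 1.52 * _unit(u_next + 0.45 * outward)
             + 1.23 * binorm),
            ("CB", "C", ca[i] + 1.53 * _unit(outward + 0.35 * binorm)),
        ]
        residues.append(atoms)
    return residues


def _to_chain(decorated, chain_id: str, rng: np.random.Generator | None,
              jitter_sd: float) -> ChainStructure:
    residues = []
    for k, atoms in enumerate(decorated):
        recs = []
        for name, element, coord in atoms:
            c = np.array(coord, dtype=float)
            if rng is not None and jitter_sd > 0:
                c = c + rng.normal(0.0, jitter_sd, 3)
            recs.append(AtomRecord(name=name, element=element, coord=c,
                                   radius=VDW_RADII.get(element, DEFAULT_RADIUS)))
        residues.append(ResidueRecord(seq_index=k, residue_name="ALA",
                                      atoms=recs, author_id=str(k + 1)))
    return ChainStructure(chain_id=chain_id, residues=residues,
                          source="synthetic")


def make_ideal_helix(n: int, seed: int = 0, jitter_sd: float = 0.0,
                     chain_id: str = "A") -> ChainStructure:
    """Ideal poly-alanine alpha-helix of ``n`` residues."""
    if n < _MIN_RESIDUES:
        raise ValueError(f"need at least {_MIN_RESIDUES} residues, got {n}")
    rng = np.random.default_rng(seed)
    return _to_chain(_decorate(_helix_trace(n)), chain_id, rng, jitter_sd)


def make_extended(n: int, seed: int = 0, jitter_sd: float = 0.0,
                  chain_id: str = "A") -> ChainStructure:
    """Fully extended (zigzag strand) poly-alanine chain."""
    if n < _MIN_RESIDUES:
        raise ValueError(f"need at least {_MIN_RESIDUES} residues, got {n}")
    rng = np.random.default_rng(seed)
    return _to_chain(_decorate(_extended_trace(n)), chain_id, rng, jitter_sd)


def _rotation_about(axis: np.ndarray, point: np.ndarray,
                    degrees: float):
    axis = _unit(axis)
    th = np.deg2rad(degrees)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)

    def apply(x: np.ndarray) -> np.ndarray:
        return (x - point) @ R.T + point

    return apply


def _min_interdomain_distance(chain: ChainStructure, n_dom: int,
                              linker: int) -> float:
    c1 = np.vstack([r.coords() for r in chain.residues[:n_dom]])
    c2 = np.vstack([r.coords() for r in chain.residues[n_dom + linker:]])
    d2 = ((c1[:, None, :] - c2[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def make_hinge_pair(n_per_domain: int = 14, linker_length: int = 6,
                    hinge_angle: float = 90.0, seed: int = 0,
                    jitter_sd: float = 0.0
                    ) -> tuple[ChainStructure, ChainStructure]:
    """Two-conformer hinge pair: helix-linker-helix, second domain rotated.

    Conformer A stacks two ideal helical domains along one axis, joined by
    an extended linker.  Conformer B has identical residues, with every atom
    past the central linker residue rigidly rotated by ``hinge_angle`` about
    an axis through that residue's CA, perpendicular to the chain axis.
    Both conformers are guaranteed to have no domain-domain atoms closer
    than the surface-contact reach (the linker is lengthened and the pair
    regenerated if the guarantee fails; after 5 attempts an error is
    raised).
    """
    if n_per_domain < _MIN_RESIDUES:
        raise ValueError(f"domains need at least {_MIN_RESIDUES} residues")
    linker = linker_length
    for _attempt in range(5):
        ca1 = _helix_trace(n_per_domain)
        top = ca1[-1]
        link = np.column_stack([
            top[0] + 0.8 * (-1.0) ** np.arange(linker),
            np.full(linker, top[1]),
            top[2] + 3.3 * (np.arange(linker) + 1.0),
        ])
        ca2 = _helix_trace(n_per_domain)
        ca2 = ca2 + (link[-1] + np.array([0.0, 0.0, 3.4]) - ca2[0])
        ca = np.vstack([ca1, link, ca2])

        rng = np.random.default_rng(seed)
        chain_a = _to_chain(_decorate(ca), "A", rng, jitter_sd)

        pivot_idx = n_per_domain + linker // 2
        pivot_ca = chain_a.residues[pivot_idx].atom("CA").coord
        rotate = _rotation_about(np.array([1.0, 0.0, 0.0]), pivot_ca,
                                 hinge_angle)
        residues_b = []
        for res in chain_a.residues:
            atoms = []
            for a in res.atoms:
                coord = rotate(a.coord) if res.seq_index > pivot_idx \
                    else a.coord.copy()
                atoms.append(AtomRecord(name=a.name, element=a.element,
                                        coord=coord, radius=a.radius))
            residues_b.append(ResidueRecord(seq_index=res.seq_index,
                                            residue_name=res.residue_name,
                                            atoms=atoms,
                                            author_id=res.author_id))
        chain_b = ChainStructure(chain_id="B", residues=residues_b,
                                 source="synthetic")

        sep_a = _min_interdomain_distance(chain_a, n_per_domain, linker)
        sep_b = _min_interdomain_distance(chain_b, n_per_domain, linker)
        if min(sep_a, sep_b) >= MIN_DOMAIN_SEPARATION:
            return chain_a, chain_b
        linker += 2
    raise RuntimeError(
        "could not satisfy the no-inter-domain-contact guarantee after 5 "
        "attempts; try a smaller hinge angle")


def make_fixture(spec: FixtureSpec):
    """Build the structure(s) described by a :class:`FixtureSpec`.

    Returns a single chain for the one-piece geometries and an (A, B) tuple
    for ``two_domain``.
    """
    if spec.geometry == "ideal_helix":
        return make_ideal_helix(spec.n_residues, spec.seed, spec.jitter_sd)
    if spec.geometry == "extended":
        return make_extended(spec.n_residues, spec.seed, spec.jitter_sd)
    if spec.geometry == "two_domain":
        n_dom = max(_MIN_RESIDUES,
                    (spec.n_residues - spec.linker_length) // 2)
        return make_hinge_pair(n_dom, spec.linker_length, spec.hinge_angle,
                               spec.seed, spec.jitter_sd)
    raise ValueError(f"unknown geometry {spec.geometry!r}")
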