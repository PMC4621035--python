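"""Default parameters for the contact-area alignment pipeline.

Every tunable of the method lives here so that a single flat ``key=value``
config file can override the whole pipeline (see :func:`load_params_file`).
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

#: Heavy-atom van der Waals radii (Å).  The published Bondi-style set for the
#: elements that occur in standard amino acids; anything else falls back to
#: DEFAULT_RADIUS.  Contact areas shift slightly if a different set is chosen.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

DEFAULT_RADIUS: float = 1.70


def radius_table_hash(table: dict[str, float] | None = None) -> str:
    """Short stable hash of a radius table, recorded in contact-matrix caches."""
    table = VDW_RADII if table is None else table
    text = ";".join(f"{k}={table[k]:.4f}" for k in sorted(table))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclasses.dataclass(frozen=True)
class SurfaceParams:
    """Residue-surface and contact-area parameters.

    c
        Density smoothness coefficient; the metaball kernel of each atom
        vanishes beyond ``c * r`` from its centre.
    voxel
        Marching-cubes grid spacing in Å.
    cutoff
        Maximum surface-to-surface distance (Å) for two residues' mesh
        triangles to count as being in contact.
    """

    c: float = 1.5
    voxel: float = 1.0
    cutoff: float = 2.8


@dataclasses.dataclass(frozen=True)
class SeedParams:
    """Seed-alignment generation parameters.

    urms_ref
        Expected minimum unit-vector RMS between two random heptapeptides;
        local-similarity scores are scaled against it.
    gap_opens / gap_extends
        The affine-penalty grid swept during seeding; only combinations with
        open >= extend are used (58 of them).
    n_suboptimal
        Suboptimal alignments generated per penalty combination, by damping
        previously-aligned score cells by 10% per round.
    tm_gap_open / tm_gap_extend
        Penalties for the TM-score refinement DP.
    tm_max_rounds
        Cap on superpose-and-realign rounds during TM refinement.
    """

    urms_ref: float = 0.917
    gap_opens: tuple[float, ...] = tuple(float(a) for a in range(0, 51, 5))
    gap_extends: tuple[float, ...] = tuple(float(b) for b in range(0, 11, 2))
    n_suboptimal: int = 4
    subopt_damping: float = 0.9
    tm_gap_open: float = 0.6
    tm_gap_extend: float = 0.0
    tm_max_rounds: int = 20


@dataclasses.dataclass(frozen=True)
class CabParams:
    """Parameters of the contact-area similarity score and its optimisation.

    gamma
        Weight for residue pairs at intermediate sequence separation (2-4)
        in the pair-similarity weight function.
    gap_open_iter / gap_extend_iter
        Affine penalties for the iterative DP over the smoothed similarity
        field.  Only the open penalty was tuned (90); extension is free.
    windows
        Sliding-window half-widths, applied in order; the window size is
        ``2 * Nw + 1`` and shrinks as the alignment stabilises.
    max_iter_per_window
        DP rounds per window before the half-width is reduced.
    pow
        Exponent applied to the total contact areas when normalising the raw
        similarity score for cross-pair comparison.
    """

    gamma: float = 0.5
    gap_open_iter: float = 90.0
    gap_extend_iter: float = 0.0
    windows: tuple[int, ...] = (5, 3, 1)
    max_iter_per_window: int = 10
    pow: float = 0.7
    s_tol: float = 1e-9


_PARAM_CLASSES = {"surface": SurfaceParams, "seed": SeedParams, "cab": CabParams}


def _coerce(value: str, like) -> object:
    if isinstance(like, tuple):
        elem = like[0] if like else 0.0
        return tuple(type(elem)(v) for v in value.replace(",", " ").split())
    return type(like)(value)


def load_params_file(path) -> dict[str, object]:
    """Parse a flat ``section.key = value`` config file.

    Returns ``{"surface": SurfaceParams, "seed": SeedParams, "cab": CabParams}``
    with any keys not mentioned left at their defaults.  Lines starting with
    ``#`` and blank lines are ignored.
    """
    overrides: dict[str, dict[str, object]] = {k: {} for k in _PARAM_CLASSES}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if "." not in key:
                raise ValueError(f"{path}:{lineno}: key must be 'section.key'")
            section, field = key.split(".", 1)
            if section not in _PARAM_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown section {section!r}")
            default = getattr(_PARAM_CLASSES[section](), field)
            overrides[section][field] = _coerce(value, default)
    return {
        name: cls(**overrides[name]) for name, cls in _PARAM_CLASSES.items()
    }


def dump_params(params: dict[str, object]) -> str:
    """Serialise the effective parameters back to the flat config format."""
    lines = []
    for section, obj in params.items():
        for field in dataclasses.fields(obj):
            value = getattr(obj, field.name)
            if isinstance(value, tuple):
                value = " ".join(str(v) for v in value)
            lines.append(f"{section}.{field.name} = {value}")
    return "\n".join(lines) + "\n"
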