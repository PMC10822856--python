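"""Landmark templates and the facial-zone registry.

Three view templates are used throughout the package: 105 landmarks for
frontal views, 73 for lateral (profile) views and 41 for external-ear
views.  A template here is an ordered set of named point blocks (face
outline, eyes, eyebrows, ...); block membership is what the texture
zones and the synthetic-cohort generator are defined against, so the
index layout is fixed and versioned with the package.

The point *coordinates* returned by :func:`template_points` are a
procedurally constructed face-like layout on a 256x256 canvas (image
convention: origin top-left, y down).  They serve as the mean shape of
the synthetic cohort generator; the pipeline itself only ever relies on
point counts and block indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CANVAS = 256  # synthetic template canvas size, pixels

VIEWS = ("frontal", "lateral_left", "lateral_right", "ear")

#: point counts per template
TEMPLATE_SIZES = {"frontal": 105, "lateral": 73, "ear": 41}

# ---------------------------------------------------------------------------
# block layout (name -> number of points, in index order)

_FRONTAL_BLOCKS = [
    ("outline", 24),
    ("forehead", 6),
    ("glabella", 4),
    ("right_eyebrow", 8),
    ("left_eyebrow", 8),
    ("right_eye", 10),
    ("left_eye", 10),
    ("nose_bridge", 4),
    ("nasal_tip", 7),
    ("philtrum", 4),
    ("mouth", 12),
    ("right_cheek", 4),
    ("left_cheek", 4),
]

_LATERAL_BLOCKS = [
    ("profile_outline", 24),
    ("vault", 12),
    ("ear_outline", 12),
    ("eye", 8),
    ("eyebrow", 6),
    ("zygoma", 5),
    ("preauricular", 6),
]

_EAR_BLOCKS = [
    ("helix", 16),
    ("antihelix", 9),
    ("concha", 8),
    ("lobe", 4),
    ("tragus", 4),
]

_BLOCKS = {"frontal": _FRONTAL_BLOCKS, "lateral": _LATERAL_BLOCKS, "ear": _EAR_BLOCKS}


def template_for_view(view: str) -> str:
    """Map a view name to its template name."""
    if view == "frontal":
        return "frontal"
    if view in ("lateral_left", "lateral_right"):
        return "lateral"
    if view == "ear":
        return "ear"
    raise ValueError(f"unknown view {view!r}")


def template_from_count(n_points: int) -> str:
    """Infer the template name from a point count (105/73/41)."""
    for name, n in TEMPLATE_SIZES.items():
        if n == n_points:
            return name
    raise ValueError(
        f"point count {n_points} matches no registered template "
        f"(expected one of {sorted(TEMPLATE_SIZES.values())})"
    )


def block_indices(template: str) -> dict[str, np.ndarray]:
    """Index arrays of each named block of a template."""
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, n in _BLOCKS[template]:
        out[name] = np.arange(start, start + n)
        start += n
    assert start == TEMPLATE_SIZES[template]
    return out


# ---------------------------------------------------------------------------
# procedural layouts


def _ellipse(cx, cy, rx, ry, n, start=-np.pi / 2, span=2 * np.pi):
    t = start + span * np.arange(n) / n
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _arc(cx, cy, rx, ry, n, a0, a1):
    t = np.linspace(a0, a1, n)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _frontal_points() -> np.ndarray:
    parts = [
        _ellipse(128, 140, 78, 95, 24),          # outline
        _ellipse(128, 70, 52, 16, 6),             # forehead
        _ellipse(128, 104, 9, 7, 4),              # glabella
        _ellipse(88, 99, 21, 6, 8),               # right eyebrow
        _ellipse(168, 99, 21, 6, 8),              # left eyebrow
        _ellipse(88, 120, 18, 7, 10),             # right eye
        _ellipse(168, 120, 18, 7, 10),            # left eye
        np.column_stack([np.full(4, 128.0), np.linspace(112, 140, 4)]),  # nose bridge
        _ellipse(128, 152, 16, 8, 7),             # nasal tip + alae
        _ellipse(128, 167, 6, 6, 4),              # philtrum
        _ellipse(128, 186, 27, 10, 12),           # mouth
        _ellipse(76, 156, 12, 12, 4),             # right cheek
        _ellipse(180, 156, 12, 12, 4),            # left cheek
    ]
    return np.vstack(parts)


def _lateral_points() -> np.ndarray:
    # right-profile convention: the face looks toward +x
    parts = [
        _arc(120, 140, 62, 96, 24, -1.35, 1.35),   # profile outline, forehead to chin
        _arc(120, 120, 70, 76, 12, 1.8, 4.6),      # cranial vault, back of head
        _ellipse(90, 150, 13, 22, 12),             # ear outline
        _ellipse(152, 116, 12, 6, 8),              # eye (lateral)
        _arc(152, 101, 16, 6, 6, np.pi, 2 * np.pi),  # eyebrow
        _ellipse(133, 142, 10, 9, 5),              # zygoma relief
        _ellipse(112, 150, 8, 14, 6),              # pre-auricular region
    ]
    return np.vstack(parts)


def _ear_points() -> np.ndarray:
    parts = [
        _ellipse(128, 128, 38, 60, 16),   # helix
        _ellipse(130, 130, 22, 38, 9),    # antihelix
        _ellipse(126, 136, 13, 20, 8),    # concha
        _ellipse(126, 196, 9, 8, 4),      # lobe
        _ellipse(106, 138, 6, 9, 4),      # tragus
    ]
    return np.vstack(parts)


_LAYOUTS = {"frontal": _frontal_points, "lateral": _lateral_points, "ear": _ear_points}


def template_points(template: str) -> np.ndarray:
    """Mean-shape coordinates (n_points, 2) of a template on the canvas."""
    pts = _LAYOUTS[template]()
    assert pts.shape == (TEMPLATE_SIZES[template], 2)
    return pts


# ---------------------------------------------------------------------------
# facial zone registry (14 zones: 11 frontal + 3 lateral)


@dataclass(frozen=True)
class ZoneSpec:
    """A landmark-defined facial zone used for texture extraction."""

    name: str
    view: str           # "frontal" or "lateral"
    polygon: tuple      # landmark indices into the view template, >= 3


def _zone_registry() -> tuple[ZoneSpec, ...]:
    fb = block_indices("frontal")
    lb = block_indices("lateral")
    frontal = [
        ("right_eye", fb["right_eye"]),
        ("left_eye", fb["left_eye"]),
        ("right_eyebrow", fb["right_eyebrow"]),
        ("left_eyebrow", fb["left_eyebrow"]),
        ("glabella", fb["glabella"]),
        ("forehead", fb["forehead"]),
        ("nasal_tip", fb["nasal_tip"]),
        ("philtrum", fb["philtrum"]),
        ("right_cheek", fb["right_cheek"]),
        ("left_cheek", fb["left_cheek"]),
        ("chin", fb["outline"][10:15]),  # bottom arc of the face outline
    ]
    lateral = [
        ("preauricular", lb["preauricular"]),
        ("lateral_eye", lb["eye"]),
        ("zygoma", lb["zygoma"]),
    ]
    zones = [ZoneSpec(n, "frontal", tuple(int(i) for i in ix)) for n, ix in frontal]
    zones += [ZoneSpec(n, "lateral", tuple(int(i) for i in ix)) for n, ix in lateral]
    return tuple(zones)


#: the 14 registered zones, in fixed registry order (11 frontal then 3 lateral)
ZONES: tuple[ZoneSpec, ...] = _zone_registry()

FRONTAL_ZONES = tuple(z for z in ZONES if z.view == "frontal")
LATERAL_ZONES = tuple(z for z in ZONES if z.view == "lateral")
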