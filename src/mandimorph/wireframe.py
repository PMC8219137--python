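"""Wireframe comparison figures of consensus configurations.

Two superimposed mean shapes are drawn as landmark-to-landmark polylines
(reference solid, comparison dashed) in an orthographic anatomical view,
with optional displacement arrows magnified by a stated factor.  Output is
deterministic SVG (fixed-precision coordinates), written with the standard
library only.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DEFAULT_LANDMARK_LABELS

__all__ = [
    "DEFAULT_EDGES",
    "Wireframe",
    "anatomical_axes",
    "project_view",
    "viewport_transform",
    "render_comparison",
    "svg_landmark_positions",
    "export_displacements",
]

#: Default mandible edge list: sigmoid notch (Co-Mn-Cs), posterior ramus
#: (Cs-Go), mandibular body (Go-Ml), symphysis chain (Id-Mns-Pg-Gn) and its
#: connections to each hemi-body.
DEFAULT_EDGES: tuple = tuple(
    [(f"Co_{s}", f"Mn_{s}") for s in "LR"]
    + [(f"Mn_{s}", f"Cs_{s}") for s in "LR"]
    + [(f"Cs_{s}", f"Go_{s}") for s in "LR"]
    + [(f"Go_{s}", f"Ml_{s}") for s in "LR"]
    + [(f"Ml_{s}", "Id") for s in "LR"]
    + [(f"Go_{s}", "Gn") for s in "LR"]
    + [("Id", "Mns"), ("Mns", "Pg"), ("Pg", "Gn")]
)


@dataclass
class Wireframe:
    """Edge list over landmark labels plus the available named views."""

    edges: tuple = DEFAULT_EDGES
    labels: tuple = DEFAULT_LANDMARK_LABELS
    views: tuple = ("lateral", "anterior")

    def __post_init__(self):
        seen = set()
        for a, b in self.edges:
            if a not in self.labels or b not in self.labels:
                raise ValueError(f"edge ({a}, {b}) references unknown landmark")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add(key)

    def edge_indices(self) -> list:
        pos = {lb: i for i, lb in enumerate(self.labels)}
        return [(pos[a], pos[b]) for a, b in self.edges]


def anatomical_axes(mean: np.ndarray, labels=DEFAULT_LANDMARK_LABELS) -> np.ndarray:
    """Rotation (3, 3) mapping a consensus into anatomical axes.

    The lateral axis comes from the bilateral ``_L``/``_R`` landmark pairs
    (their mean left-right vector defines the midsagittal normal), the
    superior axis from gnathion toward the condyles (orthogonalized), and
    the anterior axis completes the right-handed frame.  Rows of the
    returned matrix are the (anterior, lateral, superior) unit axes.
    """
    mean = np.asarray(mean, float)
    labels = list(labels)
    pairs = [
        (labels.index(lb), labels.index(lb[:-2] + "_R"))
        for lb in labels
        if lb.endswith("_L") and lb[:-2] + "_R" in labels
    ]
    if not pairs:
        raise ValueError("no bilateral _L/_R landmark pairs to define the midplane")
    lat = np.mean([mean[i] - mean[j] for i, j in pairs], axis=0)
    lat /= np.linalg.norm(lat)
    if "Gn" in labels and "Cs_L" in labels and "Cs_R" in labels:
        up = 0.5 * (mean[labels.index("Cs_L")] + mean[labels.index("Cs_R")]) - mean[
            labels.index("Gn")
        ]
    else:  # fall back to the principal axis most orthogonal to lateral
        _, _, Vt = np.linalg.svd(mean - mean.mean(axis=0))
        up = Vt[0]
    up = up - (up @ lat) * lat
    up /= np.linalg.norm(up)
    ant = np.cross(lat, up)
    return np.vstack([ant, lat, up])


def project_view(coords: np.ndarray, view: str, axes: np.ndarray) -> np.ndarray:
    """Orthographic 2D projection of (k, 3) coords into a named view.

    ``lateral`` projects onto the sagittal plane (anterior vs superior);
    ``anterior`` onto the coronal plane (lateral vs superior).
    """
    rotated = np.asarray(coords, float) @ axes.T  # columns: ant, lat, sup
    if view == "lateral":
        return rotated[:, [0, 2]]
    if view == "anterior":
        return rotated[:, [1, 2]]
    raise ValueError(f"unknown view {view!r} (expected 'lateral' or 'anterior')")


def viewport_transform(points: np.ndarray, size: float = 480.0, margin: float = 40.0):
    """Affine map from projected shape units to SVG viewport units.

    Returns ``(scale, offset)`` such that ``xy_svg = scale * (x, -y) + offset``
    (SVG y grows downward).  The scale fits the point cloud into the
    ``size`` square with the given margin; deterministic for fixed input.
    """
    pts = np.asarray(points, float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = max((hi - lo).max(), 1e-12)
    scale = (size - 2 * margin) / span
    centre = 0.5 * (lo + hi)
    offset = np.array([size / 2.0, size / 2.0]) - scale * np.array([centre[0], -centre[1]])
    return scale, offset


def _to_svg(points2d: np.ndarray, scale: float, offset: np.ndarray) -> np.ndarray:
    pts = np.asarray(points2d, float)
    return scale * np.column_stack([pts[:, 0], -pts[:, 1]]) + offset


def _fmt(v: float) -> str:
    return f"{v:.6f}"


def render_comparison(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    wireframe: Wireframe = None,
    view: str = "lateral",
    out=None,
    arrow_scale: float = 3.0,
    size: float = 480.0,
    title: str | None = None,
) -> str:
    """Write a solid-vs-dashed wireframe comparison as SVG.

    ``mean_a`` (solid) and ``mean_b`` (dashed) must already share a frame
    (superimposed).  Displacement arrows from A to B landmarks are drawn
    magnified ``arrow_scale`` times, and the magnification is stated in the
    figure legend.  Identical inputs produce byte-identical SVG.  Returns
    the SVG text; ``out`` may be a path or file object.
    """
    if wireframe is None:
        wireframe = Wireframe()
    A = np.asarray(mean_a, float)
    Bm = np.asarray(mean_b, float)
    if A.shape != Bm.shape:
        raise ValueError("mean shapes must have identical dimensions")
    axes = anatomical_axes(A, wireframe.labels)
    pa = project_view(A, view, axes)
    pb = project_view(Bm, view, axes)
    scale, offset = viewport_transform(np.vstack([pa, pb]), size=size)
    qa = _to_svg(pa, scale, offset)
    qb = _to_svg(pb, scale, offset)
    qarrow = _to_svg(pa + arrow_scale * (pb - pa), scale, offset)

    svg = ET.Element(
        "svg", xmlns="http://www.w3.org/2000/svg",
        width=_fmt(size), height=_fmt(size),
        viewBox=f"0 0 {_fmt(size)} {_fmt(size)}",
    )
    for name, pts, dash in (("shape-a", qa, None), ("shape-b", qb, "6,4")):
        g = ET.SubElement(svg, "g", id=name, fill="none")
        g.set("stroke", "#1f3d7a" if name == "shape-a" else "#b03030")
        g.set("stroke-width", "1.5")
        if dash:
            g.set("stroke-dasharray", dash)
        for i, j in wireframe.edge_indices():
            ET.SubElement(
                g, "line",
                x1=_fmt(pts[i, 0]), y1=_fmt(pts[i, 1]),
                x2=_fmt(pts[j, 0]), y2=_fmt(pts[j, 1]),
            )
    ga = ET.SubElement(svg, "g", id="landmarks-a", fill="#1f3d7a")
    for lb, (x, y) in zip(wireframe.labels, qa):
        c = ET.SubElement(ga, "circle", cx=_fmt(x), cy=_fmt(y), r="2.5")
        c.set("data-landmark", lb)
    garr = ET.SubElement(svg, "g", id="arrows")
    garr.set("stroke", "#222222")
    garr.set("stroke-width", "1.0")
    for (x0, y0), (x1, y1) in zip(qa, qarrow):
        if np.hypot(x1 - x0, y1 - y0) > 1e-9:
            ET.SubElement(garr, "line", x1=_fmt(x0), y1=_fmt(y0), x2=_fmt(x1), y2=_fmt(y1))
    legend = title or f"solid: A, dashed: B, arrows x{arrow_scale:g}"
    txt = ET.SubElement(svg, "text", x=_fmt(8.0), y=_fmt(size - 8.0))
    txt.set("font-size", "12")
    txt.set("font-family", "sans-serif")
    txt.text = legend

    body = ET.tostring(svg, encoding="unicode")
    text = '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
    if out is not None:
        if hasattr(out, "write"):
            out.write(text)
        else:
            with open(out, "w") as fh:
                fh.write(text)
    return text


def svg_landmark_positions(source) -> dict:
    """Parse a rendered SVG back into ``{landmark: (cx, cy)}`` viewport units."""
    if hasattr(source, "read"):
        root = ET.parse(source).getroot()
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = ET.fromstring(source)
    else:
        root = ET.parse(source).getroot()
    ns = {"svg": "http://www.w3.org/2000/svg"}
    out = {}
    for c in root.iterfind(".//svg:circle", ns):
        lb = c.get("data-landmark")
        if lb:
            out[lb] = (float(c.get("cx")), float(c.get("cy")))
    return out


def export_displacements(
    mean_a: np.ndarray, mean_b: np.ndarray, labels=DEFAULT_LANDMARK_LABELS
) -> pd.DataFrame:
    """Per-landmark displacement vectors B - A and their magnitudes.

    Both means must be in the same frame: each is required to be centred
    (un-superimposed translated input is rejected).  The summed squared
    magnitudes equal the squared Frobenius distance between the means.
    """
    A = np.asarray(mean_a, float)
    Bm = np.asarray(mean_b, float)
    if A.shape != Bm.shape:
        raise ValueError("mismatched landmark sets")
    if len(labels) != A.shape[0]:
        raise ValueError("labels do not match landmark count")
    tol = 1e-6 * max(1.0, float(np.abs(A).max()), float(np.abs(Bm).max()))
    for name, M in (("A", A), ("B", Bm)):
        if np.linalg.norm(M.mean(axis=0)) > tol:
            raise ValueError(
                f"mean shape {name} is not centred: superimpose the means first"
            )
    d = Bm - A
    return pd.DataFrame({
        "landmark": list(labels),
        "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
        "magnitude": np.linalg.norm(d, axis=1),
    })
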