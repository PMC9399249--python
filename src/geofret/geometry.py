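"""Wireframe-polyhedron scaffold geometry and ssDNA polymer statistics.

Idealized regular polyhedra (tetrahedron, equilateral pentagonal pyramid)
stand in for wireframe DNA-origami objects: each edge is ``edge_bp`` base
pairs of duplex at the B-form rise of 0.34 nm/bp, the centroid sits at the
origin, and named attachment sites are placed on vertices, along edges, or
at the centroid, with an optional radial offset to model overhangs and
particle radii. Distances between sites feed the FRET engine; triplets of
particle positions give bond angles, whose ensembles are summarized by a
Gaussian fit.

Also provided: the self-avoiding-walk inversion that maps a measured
radius of gyration of an ssDNA segment to its Kuhn length ``b`` via
``R_ee = b (L/b)^ν`` with the Flory exponent ``ν ≈ 0.588`` and contour
length ``L = n_nt × 0.63 nm``; persistence length is reported as ``b/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaffoldModel",
    "SiteSpec",
    "AngleSample",
    "PolymerModel",
    "build_scaffold",
    "site_distance",
    "bond_angle",
    "angle_distribution_stats",
    "saw_kuhn_from_rg",
]

RISE_PER_BP_NM = 0.34          # B-DNA axial rise
CONTOUR_PER_NT_NM = 0.63       # ssDNA contour length per nucleotide
FLORY_EXPONENT_SAW = 0.588     # 3-D self-avoiding walk
#: Default R_ee/Rg prefactor for a SAW chain (√6 in the ideal-chain limit).
RG_TO_REE_SAW = np.sqrt(6.25)

POLYHEDRA = ("tetrahedron", "pentagonal_pyramid")


def _tetrahedron_vertices(edge: float) -> np.ndarray:
    # regular tetrahedron inscribed in a cube, centroid at origin
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    v *= edge / (2.0 * np.sqrt(2.0))  # cube half-diagonal scaling
    return v


def _pentagonal_pyramid_vertices(edge: float) -> np.ndarray:
    # equilateral: all 10 edges (5 base + 5 apex) equal
    r_base = edge / (2.0 * np.sin(np.pi / 5.0))  # base circumradius
    height = np.sqrt(edge**2 - r_base**2)        # apex above base plane
    angles = 2.0 * np.pi * np.arange(5) / 5.0
    base = np.column_stack(
        [r_base * np.cos(angles), r_base * np.sin(angles), np.zeros(5)]
    )
    apex = np.array([[0.0, 0.0, height]])
    verts = np.vstack([base, apex])
    verts -= verts.mean(axis=0)  # centroid at origin
    return verts


_EDGE_LISTS = {
    "tetrahedron": [(i, j) for i in range(4) for j in range(i + 1, 4)],
    "pentagonal_pyramid": [(i, (i + 1) % 5) for i in range(5)]
    + [(i, 5) for i in range(5)],
}


@dataclass(frozen=True)
class SiteSpec:
    """Attachment-site placement: anchor + fractional position + offset.

    ``anchor_type`` is ``vertex`` (index into vertices), ``edge`` (index
    into the edge list, placed at ``fraction`` along it) or ``centroid``.
    ``radial_offset_nm`` displaces the site along the ray from the
    centroid through the anchor point (convention: +z for the centroid
    itself, whose ray is undefined).
    """

    name: str
    anchor_type: str
    index: int = 0
    fraction: float = 0.5
    radial_offset_nm: float = 0.0


@dataclass(frozen=True)
class ScaffoldModel:
    """A regular wireframe polyhedron with named sites, in nm."""

    polyhedron: str
    edge_bp: int
    rise_per_bp_nm: float
    vertices: np.ndarray = field(repr=False)
    sites: dict = field(default_factory=dict, repr=False)

    @property
    def edge_length_nm(self) -> float:
        return self.edge_bp * self.rise_per_bp_nm

    @property
    def edge_list(self) -> list[tuple[int, int]]:
        return list(_EDGE_LISTS[self.polyhedron])

    def site_position(self, name: str) -> np.ndarray:
        """Resolve a registered site to 3-D coordinates (nm)."""
        if name not in self.sites:
            raise KeyError(
                f"unknown site {name!r}; registered sites: {sorted(self.sites)}"
            )
        spec: SiteSpec = self.sites[name]
        if spec.anchor_type == "vertex":
            anchor = self.vertices[spec.index]
        elif spec.anchor_type == "edge":
            i, j = self.edge_list[spec.index]
            anchor = (1.0 - spec.fraction) * self.vertices[i] + spec.fraction * self.vertices[j]
        elif spec.anchor_type == "centroid":
            anchor = np.zeros(3)
        else:
            raise ValueError(f"unknown anchor type {spec.anchor_type!r}")
        if spec.radial_offset_nm:
            norm = np.linalg.norm(anchor)
            direction = anchor / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
            return anchor + spec.radial_offset_nm * direction
        return anchor

    def with_site(self, spec: SiteSpec) -> "ScaffoldModel":
        sites = dict(self.sites)
        sites[spec.name] = spec
        return ScaffoldModel(
            polyhedron=self.polyhedron,
            edge_bp=self.edge_bp,
            rise_per_bp_nm=self.rise_per_bp_nm,
            vertices=self.vertices,
            sites=sites,
        )


def build_scaffold(
    polyhedron: str,
    edge_bp: int,
    rise_per_bp_nm: float = RISE_PER_BP_NM,
    sites: list[SiteSpec] | None = None,
) -> ScaffoldModel:
    """Build a regular scaffold with edge length ``edge_bp × rise``.

    52 bp edges give 17.68 nm (the ~18 nm tetrahedron); 63 bp edges give
    21.42 nm (the ~21 nm pentagonal pyramid).
    """
    if polyhedron not in POLYHEDRA:
        raise ValueError(f"unknown polyhedron {polyhedron!r}; choose from {POLYHEDRA}")
    if edge_bp <= 0:
        raise ValueError("edge_bp must be > 0")
    if rise_per_bp_nm <= 0:
        raise ValueError("rise_per_bp_nm must be > 0")
    edge = edge_bp * rise_per_bp_nm
    if polyhedron == "tetrahedron":
        verts = _tetrahedron_vertices(edge)
    else:
        verts = _pentagonal_pyramid_vertices(edge)
    model = ScaffoldModel(
        polyhedron=polyhedron,
        edge_bp=edge_bp,
        rise_per_bp_nm=rise_per_bp_nm,
        vertices=verts,
        sites={},
    )
    for spec in sites or []:
        model = model.with_site(spec)
    return model


def site_distance(model: ScaffoldModel, site_a: str, site_b: str) -> float:
    """Euclidean distance in nm between two registered sites."""
    return float(
        np.linalg.norm(model.site_position(site_a) - model.site_position(site_b))
    )


def bond_angle(p_left, p_center, p_right) -> float:
    """Interior angle at ``p_center`` in degrees, in [0, 180]."""
    a = np.asarray(p_left, dtype=float) - np.asarray(p_center, dtype=float)
    b = np.asarray(p_right, dtype=float) - np.asarray(p_center, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("bond angle undefined for coincident points")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


@dataclass(frozen=True)
class AngleSample:
    """Gaussian summary of a bond-angle ensemble (degrees)."""

    angles: np.ndarray = field(repr=False)
    mean_deg: float
    sd_deg: float
    range_deg: tuple[float, float]
    fraction_in_range: float
    histogram_counts: np.ndarray = field(repr=False)
    histogram_edges: np.ndarray = field(repr=False)


def angle_distribution_stats(
    angles,
    range_deg: tuple[float, float],
    n_bins: int = 18,
) -> AngleSample:
    """Fit a Gaussian (MLE: sample mean/sd) and count the in-range fraction.

    Mirrors the TEM trimer analysis: a Gaussian is fit to the observed
    bond-angle distribution and the fraction of particles inside a stated
    angular window is reported alongside a histogram export.
    """
    arr = np.asarray(angles, dtype=float)
    if arr.size < 10:
        raise ValueError(f"need at least 10 angles, got {arr.size}")
    if np.any((arr < 0) | (arr > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    lo, hi = range_deg
    if lo >= hi:
        raise ValueError("range must satisfy lo < hi")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))  # Gaussian MLE
    frac = float(np.mean((arr >= lo) & (arr <= hi)))
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, 180.0))
    return AngleSample(
        angles=arr,
        mean_deg=mean,
        sd_deg=sd,
        range_deg=(float(lo), float(hi)),
        fraction_in_range=frac,
        histogram_counts=counts,
        histogram_edges=edges,
    )


@dataclass(frozen=True)
class PolymerModel:
    """SAW description of an ssDNA segment, all lengths in nm."""

    n_nucleotides: int
    contour_per_nt_nm: float
    contour_length_nm: float
    flory_exponent: float
    rg_to_ree: float
    rg_nm: float
    end_to_end_nm: float
    kuhn_length_nm: float

    @property
    def persistence_length_nm(self) -> float:
        """l_p = b/2 under the wormlike-chain convention used here."""
        return self.kuhn_length_nm / 2.0

    def forward_rg(self) -> float:
        """Rg implied by the stored Kuhn length (round-trip check)."""
        b, nu = self.kuhn_length_nm, self.flory_exponent
        ree = b * (self.contour_length_nm / b) ** nu
        return ree / self.rg_to_ree


def saw_kuhn_from_rg(
    rg_nm: float,
    n_nucleotides: int,
    contour_per_nt_nm: float = CONTOUR_PER_NT_NM,
    flory_exponent: float = FLORY_EXPONENT_SAW,
    rg_to_ree: float = RG_TO_REE_SAW,
) -> PolymerModel:
    """Kuhn length from a measured radius of gyration via the SAW model.

    Solves ``R_ee = b (L/b)^ν`` for ``b`` with ``R_ee = rg_to_ree × Rg``
    and ``L = n × contour_per_nt``:

    ``b = (R_ee / L^ν)^(1/(1−ν))``.

    With ν = 1/2 and rg_to_ree = √6 this reduces to the Gaussian-chain
    closed form ``b = 6 Rg²/L``. Raises if the inferred ``b`` reaches the
    contour length (chain stiffer than its own contour).
    """
    if rg_nm <= 0:
        raise ValueError("Rg must be > 0")
    if n_nucleotides < 2:
        raise ValueError("need at least 2 nucleotides")
    if not (0.0 < flory_exponent < 1.0):
        raise ValueError("flory_exponent must be in (0, 1)")
    contour = n_nucleotides * contour_per_nt_nm
    ree = rg_to_ree * rg_nm
    b = (ree / contour**flory_exponent) ** (1.0 / (1.0 - flory_exponent))
    if b >= contour:
        raise ValueError(
            f"inferred Kuhn length {b:.3g} nm >= contour length {contour:.3g} nm; "
            "the SAW mapping is invalid for so extended a chain"
        )
    return PolymerModel(
        n_nucleotides=n_nucleotides,
        contour_per_nt_nm=contour_per_nt_nm,
        contour_length_nm=contour,
        flory_exponent=flory_exponent,
        rg_to_ree=rg_to_ree,
        rg_nm=rg_nm,
        end_to_end_nm=ree,
        kuhn_length_nm=b,
    )
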