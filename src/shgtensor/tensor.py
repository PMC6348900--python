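"""Structure-tensor orientation analysis of SHG images.

The structure tensor at a pixel is the Gaussian-windowed outer product of the
intensity gradient,

    J = G_rho * [[gx^2, gx*gy], [gx*gy, gy^2]],

with gradients taken at a derivative scale sigma_g and the window at a larger
integration scale rho.  Its eigenvalues l1 >= l2 >= 0 describe local
anisotropy: the eigenvector of the *smallest* eigenvalue points along the
structure (fibers), and the coherence

    C = (l1 - l2) / (l1 + l2)  in [0, 1]

is 0 for isotropic texture and 1 for a perfectly oriented one.  Coherence is
the per-pixel degree of isotropy (DoI) reported here; its mean over valid
pixels summarizes a map.  Orientations are axial (mod 180 deg), measured
counterclockwise from +x in the displayed image.

Derived summaries follow the conventions used for corneal stroma: a
preferential-orientation (PO) histogram over [0, 180) normalized to max 1,
peak detection on the circular histogram, a structural-dispersion statistic,
and a three-way organization classification with DoI boundaries at 0.20
(nonorganized below, or when no PO exists) and 0.70 (highly aligned above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .synthetic import SHGImage

__all__ = [
    "TensorConfig",
    "OrientationField",
    "DoIMap",
    "POHistogram",
    "OrganizationClass",
    "orientation_field",
    "doi_map",
    "po_histogram",
    "detect_preferential_orientations",
    "structural_dispersion",
    "classify_organization",
    "analyze_plane",
]

# DoI class boundaries: nonorganized below 0.20 (or no PO); highly aligned
# above 0.70; partially aligned between.
DOI_NONORGANIZED = 0.20
DOI_PARTIAL_UPPER = 0.70


@dataclass(frozen=True)
class TensorConfig:
    """Scales and thresholds of the tensor analysis (lengths in um)."""

    sigma_gradient_um: float = 1.0
    sigma_window_um: float = 4.0
    bin_width_deg: float = 1.0
    coherence_weighting: bool = True
    peak_prominence: float = 0.2           # fraction of the max bin
    peak_min_separation_deg: float = 20.0
    peak_smooth_deg: float = 3.0           # circular Gaussian presmoothing
    peak_min_rel_to_mean: float = 2.0      # enrichment over uniform baseline
    doi_nonorganized_threshold: float = DOI_NONORGANIZED
    doi_partial_upper: float = DOI_PARTIAL_UPPER
    energy_floor_rel: float = 1e-6         # fraction of max tensor trace
    border_margin_px: int | None = None    # default: ceil(3*rho/pixel)

    def __post_init__(self):
        if not 0 < self.sigma_gradient_um <= self.sigma_window_um:
            raise ValueError("require 0 < sigma_gradient_um <= sigma_window_um")
        if not (180.0 / self.bin_width_deg).is_integer():
            raise ValueError("bin_width_deg must divide 180")
        for t in (self.doi_nonorganized_threshold, self.doi_partial_upper,
                  self.peak_prominence):
            if not 0 <= t <= 1:
                raise ValueError("thresholds must lie in [0, 1]")

    def margin_px(self, pixel_size_um: float) -> int:
        if self.border_margin_px is not None:
            return self.border_margin_px
        return int(math.ceil(3.0 * self.sigma_window_um / pixel_size_um))


@dataclass
class OrientationField:
    """Per-pixel axial orientation (deg, [0,180)) and tensor coherence."""

    theta_deg: np.ndarray
    coherence: np.ndarray
    valid_mask: np.ndarray
    pixel_size_um: float

    def masked_theta(self) -> np.ndarray:
        return self.theta_deg[self.valid_mask]

    def masked_coherence(self) -> np.ndarray:
        return self.coherence[self.valid_mask]


@dataclass
class DoIMap:
    """Per-pixel DoI (= tensor coherence) with its mean over valid pixels."""

    doi: np.ndarray
    mean_doi: float
    valid_mask: np.ndarray


@dataclass
class POHistogram:
    """Normalized orientation histogram over [0, 180), max bin = 1."""

    bin_centers_deg: np.ndarray
    frequency: np.ndarray
    peaks: list = field(default_factory=list)  # (angle_deg, height), by height
    sd: float = 0.0

    @property
    def bin_width_deg(self) -> float:
        return float(self.bin_centers_deg[1] - self.bin_centers_deg[0])


@dataclass(frozen=True)
class OrganizationClass:
    """Three-way arrangement class with its supporting evidence."""

    label: str          # nonorganized | partially_aligned | highly_aligned
    mean_doi: float
    n_peaks: int


# ---------------------------------------------------------------------------
# Tensor field
# ---------------------------------------------------------------------------

def orientation_field(image: SHGImage, config: TensorConfig = TensorConfig()
                      ) -> OrientationField:
    """Per-pixel orientation and coherence from the structure tensor.

    Gradients are Gaussian derivatives at ``sigma_gradient_um``; the tensor
    products are smoothed at ``sigma_window_um``; all convolutions use
    reflect boundary handling.  Pixels whose tensor trace falls below
    ``energy_floor_rel`` times the image maximum trace (no gradient energy,
    coherence undefined) and a border margin of 3 window sigmas are excluded
    from ``valid_mask``.
    """
    px = image.pixel_size_um
    sg = config.sigma_gradient_um / px
    sw = config.sigma_window_um / px
    h, w = image.shape
    if min(h, w) < 4 * sw:
        raise ValueError("image smaller than 4 window sigmas")

    img = image.intensity
    # axis 0 = rows = -y (display y points down); flip for CCW-positive angles
    gx = ndimage.gaussian_filter(img, sg, order=(0, 1), mode="reflect")
    gy = -ndimage.gaussian_filter(img, sg, order=(1, 0), mode="reflect")

    jxx = ndimage.gaussian_filter(gx * gx, sw, mode="reflect")
    jxy = ndimage.gaussian_filter(gx * gy, sw, mode="reflect")
    jyy = ndimage.gaussian_filter(gy * gy, sw, mode="reflect")

    trace = jxx + jyy
    floor = config.energy_floor_rel * trace.max() if trace.max() > 0 else 0.0

    # dominant gradient direction; structure runs perpendicular to it
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = np.mod(np.degrees(phi) + 90.0, 180.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(
            trace > floor,
            np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy ** 2) / trace,
            0.0,
        )
    coherence = np.clip(coherence, 0.0, 1.0)

    mask = trace > floor
    if floor == 0.0:
        mask = trace > 0  # constant image: nothing valid
    m = config.margin_px(px)
    if m > 0:
        border = np.zeros_like(mask)
        if h > 2 * m and w > 2 * m:
            border[m:-m, m:-m] = True
        mask &= border
    return OrientationField(theta, coherence, mask, px)


def doi_map(field_: OrientationField) -> DoIMap:
    """Degree-of-isotropy map: per-pixel coherence, mean over valid pixels."""
    if not np.any(field_.valid_mask):
        raise ValueError("empty valid mask")
    mean = float(field_.coherence[field_.valid_mask].mean())
    return DoIMap(field_.coherence, mean, field_.valid_mask)


# ---------------------------------------------------------------------------
# Orientation histogram
# ---------------------------------------------------------------------------

def po_histogram(field_: OrientationField,
                 config: TensorConfig = TensorConfig()) -> POHistogram:
    """Histogram of orientations over [0, 180), normalized to max bin = 1.

    Each pixel votes with weight equal to its coherence when
    ``coherence_weighting`` is on (structureless pixels barely vote),
    otherwise with unit weight.  Structural dispersion is attached.
    """
    if not np.any(field_.valid_mask):
        raise ValueError("empty valid mask")
    bw = config.bin_width_deg
    nbins = int(round(180.0 / bw))
    theta = field_.masked_theta()
    weights = field_.masked_coherence() if config.coherence_weighting else None
    counts, edges = np.histogram(theta, bins=nbins, range=(0.0, 180.0),
                                 weights=weights)
    centers = (edges[:-1] + edges[1:]) / 2.0
    top = counts.max()
    freq = counts / top if top > 0 else counts.astype(float)
    hist = POHistogram(centers, freq)
    hist.peaks = detect_preferential_orientations(hist, config)
    hist.sd = structural_dispersion(hist)
    return hist


def circular_separation_deg(a: float, b: float, period: float = 180.0) -> float:
    """Smallest separation of two axial angles on a circle of given period."""
    d = abs(a - b) % period
    return min(d, period - d)


def detect_preferential_orientations(hist: POHistogram,
                                     config: TensorConfig = TensorConfig()
                                     ) -> list:
    """Peaks of the circular PO histogram (period 180 deg).

    The histogram is first smoothed with a small circular Gaussian
    (``peak_smooth_deg``) so that bin-level sampling noise does not masquerade
    as structure; local maxima with prominence >= ``peak_prominence`` x the
    max bin are found on the circularly extended smoothed histogram and must
    additionally be enriched at least ``peak_min_rel_to_mean`` times over the
    histogram mean — a preferential orientation is a direction enriched over
    the uniform (isotropic) baseline, so near-flat noisy histograms report
    absence of PO.  Each surviving peak's angle is refined by the axial
    circular mean of the raw histogram mass within the minimum separation of
    the mode (a family-mean estimate: wavy fibers have a bimodal local
    tangent distribution whose lobes straddle the family mean, so the window
    must cover both lobes), and peaks are thinned greedily by height so
    survivors are
    >= ``peak_min_separation_deg`` apart.  An empty list encodes "absence of
    PO".
    """
    freq = np.asarray(hist.frequency, dtype=float)
    n = freq.size
    if n == 0 or freq.max() <= 0:
        return []
    if np.ptp(freq) == 0:
        return []  # flat histogram: every bin ties, no preferred direction
    bw = hist.bin_width_deg
    sigma_bins = config.peak_smooth_deg / bw
    smooth = ndimage.gaussian_filter1d(freq, sigma_bins, mode="wrap") \
        if sigma_bins > 0 else freq
    tiled = np.concatenate([smooth, smooth, smooth])
    prom = config.peak_prominence * smooth.max()
    idx, _ = signal.find_peaks(tiled, prominence=prom)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    baseline = config.peak_min_rel_to_mean * smooth.mean()
    half_window = int(round(config.peak_min_separation_deg / bw))
    cands = []
    floor_level = float(np.median(smooth))
    for i in idx:
        if smooth[i] < baseline:
            continue
        win = (np.arange(i - half_window, i + half_window + 1)) % n
        mass = np.clip(freq[win] - floor_level, 0.0, None)
        ang_doubled = np.radians(2.0 * hist.bin_centers_deg[win])
        # unwrap about the mode so the window is contiguous on the circle
        center = math.radians(2.0 * hist.bin_centers_deg[i])
        rel = np.angle(np.exp(1j * (ang_doubled - center)))
        if mass.sum() > 0:
            ang = (math.degrees(center + np.average(rel, weights=mass)) / 2.0) \
                % 180.0
        else:
            ang = float(hist.bin_centers_deg[i])
        cands.append((float(ang), float(freq[i])))
    cands.sort(key=lambda p: -p[1])
    kept: list = []
    for ang, height in cands:
        if all(circular_separation_deg(ang, k[0]) >= config.peak_min_separation_deg
               for k in kept):
            kept.append((ang, height))
    return kept


def structural_dispersion(hist: POHistogram) -> float:
    """Sample standard deviation of the normalized bin heights.

    Dispersion of the histogram *values*, not of the angles: a flat
    histogram scores 0 and a single sharp mode scores highest, so the
    statistic increases with alignment (and with DoI).  Heights are
    normalized to unit sum before taking the standard deviation, which makes
    the statistic a proper peakedness functional — monotone when the
    orientation distribution sharpens — independent of the max-1 display
    normalization (on a single-bin spike both normalizations coincide).
    """
    freq = np.asarray(hist.frequency, dtype=float)
    if freq.size < 2:
        return 0.0
    total = freq.sum()
    if total == 0:
        return 0.0
    return float(np.std(freq / total, ddof=1))


def classify_organization(mean_doi: float, peaks: list,
                          config: TensorConfig = TensorConfig()
                          ) -> OrganizationClass:
    """Classify an arrangement from its mean DoI and detected POs.

    nonorganized when mean DoI < 0.20 or no PO exists; highly_aligned when
    mean DoI > 0.70; partially_aligned otherwise.
    """
    if not 0.0 <= mean_doi <= 1.0:
        raise ValueError("mean_doi must lie in [0, 1]")
    n_peaks = len(peaks)
    if mean_doi < config.doi_nonorganized_threshold or n_peaks == 0:
        label = "nonorganized"
    elif mean_doi > config.doi_partial_upper:
        label = "highly_aligned"
    else:
        label = "partially_aligned"
    return OrganizationClass(label, float(mean_doi), n_peaks)


def analyze_plane(image: SHGImage, config: TensorConfig = TensorConfig()
                  ) -> dict:
    """Run the full per-plane analysis; returns a flat record.

    Keys: mean_doi, sd, peaks, n_peaks, organization, total_intensity,
    plus the underlying field/map/histogram objects.
    """
    field_ = orientation_field(image, config)
    dmap = doi_map(field_)
    hist = po_histogram(field_, config)
    cls = classify_organization(dmap.mean_doi, hist.peaks, config)
    return {
        "mean_doi": dmap.mean_doi,
        "sd": hist.sd,
        "peaks": hist.peaks,
        "n_peaks": len(hist.peaks),
        "organization": cls.label,
        "total_intensity": float(image.intensity.sum()),
        "depth_um": image.depth_um,
        "field": field_,
        "doi_map": dmap,
        "histogram": hist,
    }
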