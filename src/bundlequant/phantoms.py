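"""Synthetic ground-truth generators: hair-cell stacks, evoked-potential
recordings, and multiple sequence alignments with planted patterns.

All generators are pure functions of their spec (which embeds the seed):
identical spec → bit-identical output.  Geometry is rendered on the voxel
grid by centre-of-voxel inclusion — a voxel belongs to a shape iff its
centre lies inside — so rendered volumes converge to the analytic volumes
as the voxel size shrinks.

The imaging phantom emulates sensory hair cells: an ellipsoidal cell body
whose surface carries a membrane shell (the "basolateral" compartment), a
bundle of apical stereocilia cylinders (optionally one longer kinocilium),
and intracellular lysosome spheres with an apical placement bias.  Each
fluorescent probe is a channel with its own membrane density, stereocilia
enrichment factor E (the D4H-style probe concentrates on stereocilia
membrane; a PM-style reference labels all membrane uniformly, E = 1),
cytoplasmic background, and lysosome density (for a Lamp1-style marker).
Optics and detection are modelled as Gaussian PSF blur (applied before
noise), Poisson shot noise at a photon gain, and Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import VolumeStack

__all__ = [
    "ProbeModel",
    "PhantomSpec",
    "CellTruth",
    "GroundTruth",
    "simulate_stack",
    "AepSimSpec",
    "AepRecording",
    "simulate_aep",
    "MsaSimSpec",
    "simulate_alignment",
]


# ---------------------------------------------------------------------------
# Imaging phantom


@dataclass(frozen=True)
class ProbeModel:
    """One fluorescent channel of the phantom.

    ``membrane_density`` is the noise-free emission density (intensity
    units per voxel) of basolateral membrane; stereocilia membrane emits
    ``membrane_density * stereocilia_enrichment``; cytoplasm emits
    ``cytoplasm_density``; lysosome voxels add ``lysosome_density`` on top
    of the cytoplasmic background.
    """

    name: str
    membrane_density: float = 1.0
    stereocilia_enrichment: float = 1.0
    cytoplasm_density: float = 0.05
    lysosome_density: float = 0.0

    def __post_init__(self) -> None:
        if self.membrane_density <= 0 or self.cytoplasm_density < 0:
            raise ValueError("densities must be positive (cytoplasm may be 0)")
        if self.stereocilia_enrichment < 0 or self.lysosome_density < 0:
            raise ValueError("enrichment and lysosome density must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a synthetic two-compartment hair-cell scene.

    All phantom geometry and noise parameters are artifact choices for
    validation — they do not reconstruct any real specimen.  Lengths in
    µm, densities in intensity units per voxel.
    """

    n_cells: int = 4
    cell_semi_axes_um: tuple[float, float, float] = (4.0, 2.5, 2.5)  # (z, y, x)
    membrane_thickness_um: float = 0.4
    n_stereocilia: int = 9
    stereocilium_radius_um: float = 0.25
    stereocilium_length_um: float = 3.0
    kinocilium_length_um: float | None = None
    probes: tuple[ProbeModel, ...] = (
        ProbeModel("PM", stereocilia_enrichment=1.0),
        ProbeModel("D4H", stereocilia_enrichment=8.0),
    )
    lysosomes_per_cell: int = 3
    lysosome_diameter_um: tuple[float, float] = (0.8, 0.15)  # (mean, sd)
    enlarged_fraction: float = 0.0
    enlarged_diameter_um: float = 2.5
    apical_bias: float = 0.8
    photon_gain: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    psf_sigma_um: float = 0.15
    voxel_size_um: tuple[float, float, float] = (0.3, 0.15, 0.15)
    stack_shape: tuple[int, int, int] | None = None  # (z, y, x); None = auto
    cell_spacing_um: float = 7.0
    margin_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.cell_semi_axes_um) <= 0 or self.membrane_thickness_um <= 0:
            raise ValueError("cell semi-axes and membrane thickness must be > 0")
        if self.membrane_thickness_um >= min(self.cell_semi_axes_um):
            raise ValueError("membrane thickness must be smaller than every semi-axis")
        if self.stereocilium_radius_um <= 0 or self.stereocilium_length_um <= 0:
            raise ValueError("stereocilium dimensions must be > 0")
        if not 0.0 <= self.enlarged_fraction <= 1.0:
            raise ValueError("enlarged_fraction must lie in [0, 1]")
        if not 0.0 <= self.apical_bias <= 1.0:
            raise ValueError("apical_bias must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel size components must be > 0")
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be > 0")
        if self.psf_sigma_um < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma_um and read_noise_sd must be >= 0")

    def resolved_shape(self) -> tuple[int, int, int]:
        """Stack shape in voxels, auto-sized from the geometry if unset."""
        if self.stack_shape is not None:
            return tuple(int(n) for n in self.stack_shape)
        az, ay, ax = self.cell_semi_axes_um
        top = self.stereocilium_length_um
        if self.kinocilium_length_um:
            top = max(top, self.kinocilium_length_um)
        z_um = self.margin_um + top + 2 * az + self.margin_um
        y_um = 2 * (ay + self.margin_um)
        x_um = self.margin_um * 2 + self.cell_spacing_um * (self.n_cells - 1) + 2 * ax
        dz, dy, dx = self.voxel_size_um
        return (
            int(np.ceil(z_um / dz)),
            int(np.ceil(y_um / dy)),
            int(np.ceil(x_um / dx)),
        )


@dataclass
class CellTruth:
    """Ground-truth voxel masks and parameters for one rendered cell.

    Compartment masks are pairwise disjoint: stereocilia take precedence
    over the membrane shell, lysosomes carve out cytoplasm.
    """

    cell_id: int
    center_um: tuple[float, float, float]
    stereocilia: np.ndarray
    basolateral: np.ndarray
    cytoplasm: np.ndarray
    lysosomes: list[np.ndarray]
    lysosome_diameters_um: list[float]
    kinocilium: np.ndarray | None = None
    has_enlarged: bool = False


@dataclass
class GroundTruth:
    """Scene-level ground truth: per-cell masks plus the generating spec."""

    cells: list[CellTruth]
    spec: PhantomSpec

    def union(self, compartment: str) -> np.ndarray:
        """Union of one compartment's masks over all cells."""
        masks = []
        for c in self.cells:
            if compartment == "lysosomes":
                masks.extend(c.lysosomes)
            else:
                m = getattr(c, compartment)
                if m is not None:
                    masks.append(m)
        if not masks:
            shape = self.spec.resolved_shape()
            return np.zeros(shape, dtype=bool)
        return np.logical_or.reduce(masks)

    def cell_masks(self) -> dict[int, np.ndarray]:
        """Whole-cell masks (body + stereocilia) keyed by cell id."""
        out = {}
        for c in self.cells:
            m = c.stereocilia | c.basolateral | c.cytoplasm
            for lys in c.lysosomes:
                m = m | lys
            out[c.cell_id] = m
        return out


def _voxel_centers(shape, voxel_size):
    axes = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(Z, Y, X, center, semi):
    cz, cy, cx = center
    az, ay, ax = semi
    return ((Z - cz) / az) ** 2 + ((Y - cy) / ay) ** 2 + ((X - cx) / ax) ** 2 <= 1.0


def _cylinder_mask(Z, Y, X, center_yx, radius, z_lo, z_hi):
    cy, cx = center_yx
    return (
        ((Y - cy) ** 2 + (X - cx) ** 2 <= radius**2)
        & (Z >= z_lo)
        & (Z <= z_hi)
    )


def _sphere_mask(Z, Y, X, center, radius):
    cz, cy, cx = center
    return (Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= radius**2


def simulate_stack(spec: PhantomSpec) -> tuple[VolumeStack, GroundTruth]:
    """Render a multi-channel hair-cell phantom with ground-truth masks.

    Raises ``ValueError`` if any cell's geometry would fall outside the
    stack bounds.
    """
    shape = spec.resolved_shape()
    dz, dy, dx = spec.voxel_size_um
    extents_um = tuple(n * v for n, v in zip(shape, spec.voxel_size_um))
    Z, Y, X = _voxel_centers(shape, spec.voxel_size_um)

    az, ay, ax = spec.cell_semi_axes_um
    top_len = spec.stereocilium_length_um
    if spec.kinocilium_length_um:
        top_len = max(top_len, spec.kinocilium_length_um)

    ss = np.random.SeedSequence(spec.seed)
    scene_rng = np.random.default_rng(ss.spawn(1)[0])
    cell_seeds = ss.spawn(spec.n_cells + 1)[1:]

    cells: list[CellTruth] = []
    for i in range(spec.n_cells):
        rng = np.random.default_rng(cell_seeds[i])
        cx = spec.margin_um + ax + spec.cell_spacing_um * i
        cy = extents_um[1] / 2.0
        cz = spec.margin_um + top_len + az  # apex sits below the stereocilia
        # geometry bounds check (fail loudly, never clip silently)
        if (
            cz + az > extents_um[0] + 1e-9
            or cz - az - top_len < -1e-9
            or cy - ay < -1e-9
            or cy + ay > extents_um[1] + 1e-9
            or cx - ax < -1e-9
            or cx + ax > extents_um[2] + 1e-9
        ):
            raise ValueError(
                f"cell {i} at ({cz:.2f}, {cy:.2f}, {cx:.2f}) µm exceeds the "
                f"stack extents {tuple(round(e, 2) for e in extents_um)} µm; "
                "enlarge stack_shape or shrink the geometry"
            )

        outer = _ellipsoid_mask(Z, Y, X, (cz, cy, cx), (az, ay, ax))
        t = spec.membrane_thickness_um
        inner = _ellipsoid_mask(Z, Y, X, (cz, cy, cx), (az - t, ay - t, ax - t))
        membrane = outer & ~inner

        # stereocilia: a jittered grid of vertical cylinders on the apex
        n_st = spec.n_stereocilia
        side = int(np.ceil(np.sqrt(n_st)))
        pitch = max(2.5 * spec.stereocilium_radius_um, 0.6)
        offsets = []
        for g in range(n_st):
            gy, gx = divmod(g, side)
            offsets.append(
                (
                    (gy - (side - 1) / 2.0) * pitch,
                    (gx - (side - 1) / 2.0) * pitch,
                )
            )
        jitter = rng.uniform(-0.1, 0.1, size=(n_st, 2))
        z_apex = cz - az
        stereo = np.zeros(shape, dtype=bool)
        for (oy, ox), (jy, jx) in zip(offsets, jitter):
            stereo |= _cylinder_mask(
                Z,
                Y,
                X,
                (cy + oy + jy, cx + ox + jx),
                spec.stereocilium_radius_um,
                z_apex - spec.stereocilium_length_um,
                z_apex,
            )

        kino = None
        if spec.kinocilium_length_um:
            kino_y = cy + (side / 2.0 + 0.5) * pitch
            kino = _cylinder_mask(
                Z,
                Y,
                X,
                (kino_y, cx),
                spec.stereocilium_radius_um,
                z_apex - spec.kinocilium_length_um,
                z_apex,
            )
            kino &= ~stereo

        membrane = membrane & ~stereo  # stereocilia take precedence in overlaps
        if kino is not None:
            membrane = membrane & ~kino
        cytoplasm = inner & ~stereo

        # lysosomes inside the inner ellipsoid, biased to the apical half
        lysos: list[np.ndarray] = []
        diams: list[float] = []
        has_enlarged = bool(rng.random() < spec.enlarged_fraction)
        n_lys = spec.lysosomes_per_cell + (1 if has_enlarged else 0)
        mean_d, sd_d = spec.lysosome_diameter_um
        for j in range(n_lys):
            enlarged_vesicle = has_enlarged and j == 0
            if enlarged_vesicle:
                d = spec.enlarged_diameter_um
            else:
                d = float(np.clip(rng.normal(mean_d, sd_d), 0.2, 1.9))
            r = d / 2.0
            # sample a centre from the ellipsoid shrunk by (t + r) per axis
            sz, sy, sx = (max(a - t - r, 1e-3) for a in (az, ay, ax))
            for _attempt in range(200):
                u = rng.uniform(-1, 1, size=3)
                if (u**2).sum() > 1:
                    continue
                apical = rng.random() < spec.apical_bias
                uz = -abs(u[0]) if apical else u[0]
                c = (cz + uz * sz, cy + u[1] * sy, cx + u[2] * sx)
                break
            else:  # pragma: no cover - rejection loop virtually always succeeds
                c = (cz, cy, cx)
            m = _sphere_mask(Z, Y, X, c, r) & inner
            lysos.append(m)
            diams.append(d)
            cytoplasm &= ~m

        cells.append(
            CellTruth(
                cell_id=i,
                center_um=(cz, cy, cx),
                stereocilia=stereo,
                basolateral=membrane,
                cytoplasm=cytoplasm,
                lysosomes=lysos,
                lysosome_diameters_um=diams,
                kinocilium=kino,
                has_enlarged=has_enlarged,
            )
        )

    truth = GroundTruth(cells=cells, spec=spec)

    stereo_all = truth.union("stereocilia")
    membrane_all = truth.union("basolateral")
    cyto_all = truth.union("cytoplasm")
    lyso_all = truth.union("lysosomes")
    kino_all = truth.union("kinocilium") if spec.kinocilium_length_um else None

    channels = []
    sigma_vox = tuple(spec.psf_sigma_um / v for v in spec.voxel_size_um)
    for probe in spec.probes:
        density = np.zeros(shape, dtype=np.float64)
        density[cyto_all] = probe.cytoplasm_density
        density[lyso_all] = probe.cytoplasm_density + probe.lysosome_density
        density[membrane_all] = probe.membrane_density
        if kino_all is not None:
            density[kino_all] = probe.membrane_density
        density[stereo_all] = probe.membrane_density * probe.stereocilia_enrichment
        if spec.psf_sigma_um > 0:
            density = ndimage.gaussian_filter(density, sigma=sigma_vox)
        expected = density * spec.photon_gain
        if spec.shot_noise:
            signal = scene_rng.poisson(expected).astype(np.float64)
        else:
            signal = expected
        if spec.read_noise_sd > 0:
            signal = signal + scene_rng.normal(0.0, spec.read_noise_sd, size=shape)
        channels.append(np.clip(signal, 0.0, None))

    stack = VolumeStack(
        np.stack(channels),
        spec.voxel_size_um,
        tuple(p.name for p in spec.probes),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Evoked-potential simulation


@dataclass(frozen=True)
class AepSimSpec:
    """Stimulus-locked evoked-potential simulation.

    The response to a tone pip at ``level`` dB is the response template
    scaled by ``A(level) = a_max * logistic((level - threshold) / slope_db)``
    (``slope_db == 0`` degenerates to a hard step: 0 below threshold,
    ``a_max`` at or above), inserted ``latency_ms`` after stimulus onset
    into Gaussian background noise.
    """

    sample_rate: float = 8000.0
    frequencies: tuple[float, ...] = (200.0,)
    levels: tuple[float, ...] = tuple(float(v) for v in range(160, 115, -5))
    epochs: int = 30
    thresholds_db: tuple[float, ...] = (140.0,)
    a_max: float = 1.0
    slope_db: float = 1.0
    latency_ms: float = 5.0
    noise_sd: float = 0.1
    inter_stimulus_ms: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l2 >= l1 for l1, l2 in zip(self.levels, self.levels[1:])):
            raise ValueError(f"levels must be strictly descending, got {self.levels}")
        if self.sample_rate <= 2 * max(self.frequencies):
            raise ValueError("sample rate must exceed twice the highest frequency")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.thresholds_db) != len(self.frequencies):
            raise ValueError("one threshold per frequency required")
        if self.a_max < 0 or self.noise_sd < 0 or self.slope_db < 0:
            raise ValueError("a_max, noise_sd and slope_db must be >= 0")


@dataclass
class AepRecording:
    """Continuous trace plus the stimulus event log (onset s, Hz, dB)."""

    trace: np.ndarray
    sample_rate: float
    events: list[tuple[float, float, float]]


def response_amplitude(level: float, threshold: float, a_max: float, slope_db: float) -> float:
    """Level-dependent response amplitude A(level)."""
    if slope_db == 0:
        return a_max if level >= threshold else 0.0
    return float(a_max / (1.0 + np.exp(-(level - threshold) / slope_db)))


def simulate_aep(spec: AepSimSpec) -> tuple[AepRecording, dict[float, float]]:
    """Simulate a stimulus-locked recording; returns (recording, true θ per Hz)."""
    from .aep import make_tone_pip  # template = one Blackman-windowed cycle

    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    isi = int(round(spec.inter_stimulus_ms / 1000.0 * fs))
    latency = int(round(spec.latency_ms / 1000.0 * fs))
    n_events = len(spec.frequencies) * len(spec.levels) * spec.epochs
    n_samples = n_events * isi + isi
    trace = (
        rng.normal(0.0, spec.noise_sd, size=n_samples)
        if spec.noise_sd > 0
        else np.zeros(n_samples)
    )
    events: list[tuple[float, float, float]] = []
    pos = isi // 2
    for freq, theta in zip(spec.frequencies, spec.thresholds_db):
        template = make_tone_pip(freq, duration_s=1.0 / freq, sample_rate=fs).samples
        for level in spec.levels:
            amp = response_amplitude(level, theta, spec.a_max, spec.slope_db)
            for _ in range(spec.epochs):
                start = pos + latency
                if start + template.size > n_samples:
                    raise ValueError("epoch window exceeds trace length")
                trace[start : start + template.size] += amp * template
                events.append((pos / fs, freq, level))
                pos += isi
    rec = AepRecording(trace=trace, sample_rate=fs, events=events)
    truth = dict(zip(spec.frequencies, spec.thresholds_db))
    return rec, truth


# ---------------------------------------------------------------------------
# Alignment simulation


@dataclass(frozen=True)
class MsaSimSpec:
    """Alignment with a planted conserved pattern.

    Planted columns draw from the planted pattern's position sets: the
    consensus residue with probability ``1 - within_class_rate``, otherwise
    a uniform draw from the rest of the position's allowed set
    (``across_class_rate`` > 0 additionally substitutes residues from
    outside the set at that rate).  Background columns are i.i.d. uniform
    over the 20 residues.  Gaps are inserted in background columns only.
    """

    n_sequences: int = 60
    length: int = 40
    planted_pattern: str = "[pi]-[ST]-[Omega]-[ST]-[Psi]-[zeta]-[zeta]-[Omega]"
    planted_column: int = 10
    within_class_rate: float = 0.3
    across_class_rate: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.within_class_rate, self.across_class_rate, self.gap_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be >= 1")


def simulate_alignment(spec: MsaSimSpec) -> list[str]:
    """Generate equal-length sequences with the pattern planted at a column."""
    from .motif import AMINO_ACIDS, parse_pattern

    pattern = parse_pattern(spec.planted_pattern)
    width = len(pattern.positions)
    if any(p.kind == "gap" for p in pattern.positions):
        raise ValueError("planted patterns must be gap-free (fixed width)")
    if spec.planted_column + width > spec.length:
        raise ValueError(
            f"planted pattern of width {width} at column {spec.planted_column} "
            f"does not fit in length {spec.length}"
        )
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus = [sorted(p.allowed)[0] for p in pattern.positions]

    rows: list[str] = []
    for _ in range(spec.n_sequences):
        seq = list(rng.choice(aa, size=spec.length))
        if spec.gap_rate > 0:
            gaps = rng.random(spec.length) < spec.gap_rate
            for k in np.flatnonzero(gaps):
                seq[k] = "-"
        for off, pos in enumerate(pattern.positions):
            col = spec.planted_column + off
            allowed = sorted(pos.allowed)
            res = consensus[off]
            if len(allowed) > 1 and rng.random() < spec.within_class_rate:
                others = [r for r in allowed if r != res]
                res = others[rng.integers(len(others))]
            if spec.across_class_rate > 0 and rng.random() < spec.across_class_rate:
                outside = [r for r in AMINO_ACIDS if r not in pos.allowed]
                if outside:
                    res = outside[rng.integers(len(outside))]
            seq[col] = res
        rows.append("".join(seq))
    return rows


def write_alignment_fasta(path, rows: list[str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(row), id=f"seq{i:04d}", description="") for i, row in enumerate(rows)
    ]
    SeqIO.write(records, str(path), "fasta")
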