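"""Seeded synthetic cohorts emulating the statistical structure of a
family-clustered task-fMRI study.

The generator produces everything the prediction pipeline consumes:

* a subject table with family structure, a latent general-ability value
  ``g``, ten behavioral test scores with a bifactor (general + four group
  factors) covariance structure, an optional retest session, and nuisance
  covariates (age, handedness, gender, brain volume, reconstruction
  version, per-task mean framewise displacement);
* per-contrast voxel maps in which a demand-scaled frontoparietal (FPN)
  activation / default-mode (DMN) deactivation offset is superimposed on a
  small number of smooth, network-localized component patterns, one of
  which expresses the latent ``g`` in proportion to the contrast's
  cognitive demand, plus a motion-coupled confound pattern and white noise;
* a 7-network voxel parcellation;
* ROI time series with a low-rank, g-coupled correlation structure and
  motion traces with injected spikes, for the resting-state comparator.

No spatial geometry beyond a 1-D voxel ordering is simulated: every
downstream computation treats maps as vectors, so smoothness is imposed by
moving-average kernels within network blocks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "NetworkParcellation",
    "DEFAULT_CONTRASTS",
    "TEST_NAMES",
    "default_behavior_loadings",
    "make_parcellation",
    "generate_cohort",
    "generate_contrast_maps",
    "generate_roi_timeseries",
]

#: The ten cognitive tests of the behavioral battery (NIH Toolbox and Penn
#: battery measures), grouped as crystallized / speed / memory / visuospatial.
TEST_NAMES = [
    "PicVocab", "ReadEng",                      # crystallized
    "CardSort", "Flanker", "ProcSpeed",         # processing speed
    "PicSeq", "ListSort", "WordMem",            # memory
    "Matrices", "LineOrient",                   # visuospatial
]

_TEST_BLOCKS = [(0, 2), (2, 5), (5, 8), (8, 10)]

#: Default 15 task contrasts with a per-contrast cognitive-demand level in
#: [0, 1].  Demand controls both the FPN/DMN mean activation offset and how
#: strongly the g-coupled component is expressed; executive contrasts
#: (working memory, relational reasoning, mental arithmetic) are the most
#: demanding, passive/motor contrasts the least.
DEFAULT_CONTRASTS: dict[str, float] = {
    "2bk-0bk": 1.00,
    "2bk": 0.90,
    "Math-Story": 0.85,
    "Rel-Match": 0.80,
    "Random": 0.62,
    "0bk": 0.60,
    "TOM": 0.58,
    "Reward": 0.55,
    "Rel": 0.52,
    "Match": 0.50,
    "Punish": 0.45,
    "TOM-Random": 0.40,
    "Faces-Shapes": 0.38,
    "Motor": 0.15,
    "Punish-Reward": 0.08,
}

#: Yeo-style 7-network labeling used for the demand analysis.
NETWORK_NAMES = {
    1: "Visual", 2: "Somatomotor", 3: "DorsalAttention", 4: "VentralAttention",
    5: "Limbic", 6: "FPN", 7: "DMN",
}


def default_behavior_loadings() -> tuple[np.ndarray, np.ndarray]:
    """Default bifactor loading configuration: general 0.7 on all ten tests,
    group 0.4 in blocks of (2, 3, 3, 2)."""
    general = np.full(10, 0.7)
    group = np.zeros((10, 4))
    for k, (a, b) in enumerate(_TEST_BLOCKS):
        group[a:b, k] = 0.4
    return general, group


@dataclass
class SyntheticSpec:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: a
    967-subject family-clustered sample, ten bifactor-structured tests, 15
    task contrasts with graded cognitive demand, and a g-signal strength
    that yields cross-validated prediction accuracy in the mid-0.5 range
    for the most demanding contrast.
    """

    n_subjects: int = 967
    #: probability of family sizes 1..5 (the real family-size distribution
    #: is not public; these are plausible twin-study proportions)
    family_size_distribution: tuple[float, ...] = (0.45, 0.35, 0.12, 0.06, 0.02)
    n_voxels: int = 2000
    n_networks: int = 7
    n_signal_components: int = 5
    #: effect size linking latent g to the demand-scaled signal component
    gca_coupling: float = 0.7
    #: per-contrast cognitive demand in [0, 1]
    demand_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRASTS))
    #: voxel noise standard deviation in the maps
    noise_sd: float = 0.5
    #: FPN activation (and DMN deactivation) amplitude at demand = 1
    activation_amplitude: float = 1.0
    #: SDs of the component expression scores, descending
    component_score_sds: tuple[float, ...] = (4.0, 3.0, 2.5, 2.0, 1.5)
    behavior_general_loadings: np.ndarray = None
    behavior_group_loadings: np.ndarray = None
    #: share of latent-g variance common to a family
    family_icc: float = 0.4
    #: motion-to-map and motion-to-g coupling
    confound_strength: float = 0.2
    #: target test-retest correlation of each behavioral score
    retest_reliability: float = 0.78
    seed: int = 0

    def __post_init__(self):
        if self.behavior_general_loadings is None or self.behavior_group_loadings is None:
            gen, grp = default_behavior_loadings()
            if self.behavior_general_loadings is None:
                self.behavior_general_loadings = gen
            if self.behavior_group_loadings is None:
                self.behavior_group_loadings = grp
        self.behavior_general_loadings = np.asarray(
            self.behavior_general_loadings, dtype=float)
        self.behavior_group_loadings = np.asarray(
            self.behavior_group_loadings, dtype=float)
        self.validate()

    def validate(self) -> None:
        p = np.asarray(self.family_size_distribution, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("family_size_distribution must be a probability "
                             "vector over sizes 1..5")
        for name, d in self.demand_levels.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"demand level for {name!r} outside [0, 1]")
        if self.noise_sd < 0 or self.family_icc < 0 or self.family_icc > 1:
            raise ValueError("variance parameters must be valid")
        if not 0.0 <= self.retest_reliability <= 1.0:
            raise ValueError("retest_reliability must be in [0, 1]")
        lg = self.behavior_general_loadings
        lf = self.behavior_group_loadings
        if lg.shape != (10,) or lf.shape != (10, 4):
            raise ValueError("behavior loadings must be 10x1 general and "
                             "10x4 group")
        if np.any(np.abs(lg) > 1) or np.any(np.abs(lf) > 1):
            raise ValueError("loading magnitudes must be <= 1")
        uniq = 1.0 - lg**2 - (lf**2).sum(axis=1)
        if np.any(uniq < 0):
            raise ValueError("loadings imply negative unique variance")
        if len(self.component_score_sds) < self.n_signal_components:
            raise ValueError("need one score SD per signal component")

    @property
    def unique_variances(self) -> np.ndarray:
        return (1.0 - self.behavior_general_loadings**2
                - (self.behavior_group_loadings**2).sum(axis=1))


@dataclass
class NetworkParcellation:
    """Voxel-to-network labeling (integers 1..n_networks)."""

    labels: np.ndarray               # (n_voxels,), values 1..n_networks
    names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not set(present) <= set(self.names):
            raise ValueError("unnamed network labels present")
        for want in ("FPN", "DMN"):
            lab = self.label_of(want)
            if not np.any(self.labels == lab):
                raise ValueError(f"{want} network is empty")

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    @property
    def n_networks(self) -> int:
        return len(self.names)


def _rng_for(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    """Independent, reproducible substream keyed by (seed, stream name)."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), key]))


def make_parcellation(spec: SyntheticSpec) -> NetworkParcellation:
    """Contiguous-block 7-network labeling of the voxel ordering.

    Block sizes are fixed fractions of n_voxels, loosely matching the
    relative cortical extent of the seven networks.
    """
    fractions = np.array([0.19, 0.17, 0.10, 0.10, 0.07, 0.15, 0.22])
    fractions = fractions[: spec.n_networks]
    fractions = fractions / fractions.sum()
    sizes = np.floor(fractions * spec.n_voxels).astype(int)
    sizes[-1] += spec.n_voxels - sizes.sum()
    labels = np.repeat(np.arange(1, spec.n_networks + 1), sizes)
    names = {k: v for k, v in NETWORK_NAMES.items() if k <= spec.n_networks}
    return NetworkParcellation(labels=labels, names=names)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticSpec, include_retest: bool = True) -> pd.DataFrame:
    """Draw a family-clustered cohort with bifactor behavioral scores.

    Families are drawn from ``family_size_distribution`` until
    ``n_subjects`` is reached (the last family is truncated).  Latent
    general ability is the sum of a family effect (variance share
    ``family_icc``) and an individual effect, tilted by the motion
    confound.  Test j is
    ``lambda_g_j * g + sum_f lambda_f_j * f + sqrt(psi_j) * e``, unit
    variance in the population.
    """
    spec.validate()
    rng = _rng_for(spec, "cohort")
    n = spec.n_subjects

    sizes = []
    total = 0
    pvec = np.asarray(spec.family_size_distribution, dtype=float)
    while total < n:
        s = int(rng.choice(np.arange(1, len(pvec) + 1), p=pvec))
        s = min(s, n - total)
        sizes.append(s)
        total += s
    family_id = np.repeat(np.arange(len(sizes)), sizes)

    fam_eff = rng.standard_normal(len(sizes))[family_id]
    ind_eff = rng.standard_normal(n)
    g_core = (np.sqrt(spec.family_icc) * fam_eff
              + np.sqrt(1.0 - spec.family_icc) * ind_eff)

    # Motion propensity: lognormal mean-FD around 0.15 mm, task-specific
    # jitter applied per contrast below.
    log_fd = rng.normal(np.log(0.15), 0.35, size=n)
    fd_z = (log_fd - np.log(0.15)) / 0.35
    c = spec.confound_strength
    g = (g_core - c * fd_z) / np.sqrt(1.0 + c**2)

    lg = spec.behavior_general_loadings
    lf = spec.behavior_group_loadings
    psi = spec.unique_variances
    factors = rng.standard_normal((n, 4))
    eps = rng.standard_normal((n, 10))
    scores = np.outer(g, lg) + factors @ lf.T + eps * np.sqrt(psi)

    data = {
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "family_id": [f"F{f:04d}" for f in family_id],
        "age": rng.uniform(22.0, 36.0, size=n),
        "handedness": np.round(
            np.where(rng.random(n) < 0.9,
                     rng.uniform(40, 100, size=n),
                     rng.uniform(-100, 40, size=n)), 1),
        "gender": np.where(rng.random(n) < 0.5, "M", "F"),
        "recon_version": np.where(rng.random(n) < 0.6, "r227", "r177"),
        "latent_g": g,
    }
    data["age_sq"] = data["age"] ** 2
    data["brain_volume"] = (rng.normal(1.10e6, 1.0e5, size=n)
                            + 5.0e4 * (data["gender"] == "M"))
    base_fd = np.exp(log_fd)
    data["mean_fd"] = base_fd
    for contrast in spec.demand_levels:
        data[f"fd_{contrast}"] = base_fd * np.exp(
            rng.normal(0.0, 0.15, size=n))

    for j, name in enumerate(TEST_NAMES):
        data[name] = scores[:, j]
    if include_retest:
        rho = spec.retest_reliability
        noise2 = rng.standard_normal((n, 10))
        retest = rho * scores + np.sqrt(1.0 - rho**2) * noise2
        for j, name in enumerate(TEST_NAMES):
            data[f"retest_{name}"] = retest[:, j]

    table = pd.DataFrame(data)
    if table["subject_id"].duplicated().any():
        raise AssertionError("duplicate subject ids")
    return table


# ---------------------------------------------------------------------------
# Contrast maps
# ---------------------------------------------------------------------------

def _smooth_patterns(rng, labels, n_patterns, kernel: int = 15):
    """Unit-norm, network-localized smooth patterns over the voxel ordering.

    Each pattern concentrates on two randomly chosen networks (white noise
    there, zero elsewhere) and is smoothed with a moving average within the
    1-D ordering.
    """
    m = labels.shape[0]
    networks = np.unique(labels)
    out = np.zeros((n_patterns, m))
    box = np.ones(kernel) / kernel
    for k in range(n_patterns):
        chosen = rng.choice(networks, size=2, replace=False)
        raw = rng.standard_normal(m) * np.isin(labels, chosen)
        sm = np.convolve(raw, box, mode="same")
        out[k] = sm / np.linalg.norm(sm)
    return out


def generate_contrast_maps(subjects: pd.DataFrame,
                           parcellation: NetworkParcellation,
                           spec: SyntheticSpec,
                           contrast_name: str) -> np.ndarray:
    """Subjects-by-voxels map matrix for one task contrast.

    map_i = demand * amplitude * (FPN indicator - DMN indicator)
            + sum_k s_ik C_k + confound * meanFD_i * C_motion + noise,
    with the first component's expression score g-coupled in proportion to
    demand: s_i1 ~ scaled(gca_coupling * demand * g_i + eta_i).
    """
    if contrast_name not in spec.demand_levels:
        raise KeyError(f"unknown contrast {contrast_name!r}")
    if parcellation.labels.shape[0] != spec.n_voxels:
        raise ValueError("parcellation length != n_voxels")
    n = len(subjects)
    demand = float(spec.demand_levels[contrast_name])

    pattern_rng = _rng_for(spec, "patterns")
    C = _smooth_patterns(pattern_rng, parcellation.labels,
                         spec.n_signal_components)
    C_motion = _smooth_patterns(pattern_rng, parcellation.labels, 1)[0]

    rng = _rng_for(spec, f"maps:{contrast_name}")
    g = subjects["latent_g"].to_numpy()
    sds = np.asarray(spec.component_score_sds[: spec.n_signal_components])

    S = rng.standard_normal((n, spec.n_signal_components)) * sds
    cd = spec.gca_coupling * demand
    eta = rng.standard_normal(n)
    S[:, 0] = sds[0] * (cd * g + eta) / np.sqrt(cd**2 + 1.0)

    fpn = parcellation.mask("FPN").astype(float)
    dmn = parcellation.mask("DMN").astype(float)
    offset = demand * spec.activation_amplitude * (fpn - dmn)

    fd = subjects[f"fd_{contrast_name}"].to_numpy()
    fd_z = (np.log(fd) - np.log(0.15)) / 0.35

    maps = (offset[None, :]
            + S @ C
            + spec.confound_strength * fd_z[:, None] * C_motion[None, :]
            + spec.noise_sd * rng.standard_normal((n, spec.n_voxels)))
    return maps


# ---------------------------------------------------------------------------
# Resting-state ROI time series
# ---------------------------------------------------------------------------

def generate_roi_timeseries(subjects: pd.DataFrame, n_rois: int = 264,
                            n_frames: int = 400,
                            spec: SyntheticSpec | None = None,
                            n_latent: int = 10):
    """Per-subject ROI time series plus 6-parameter motion traces.

    Time series follow a low-rank factor model whose first latent factor's
    loadings scale with the subject's g, so between-ROI correlations carry
    a g signal; motion traces are smooth random walks with seeded spike
    frames so framewise-displacement screening is exercised.

    Returns (timeseries (n, n_frames, n_rois), motion (n, n_frames, 6)).
    """
    if spec is None:
        spec = SyntheticSpec()
    if n_rois <= 0 or n_frames <= 50:
        raise ValueError("need positive n_rois and n_frames > 50")
    rng = _rng_for(spec, "timeseries")
    n = len(subjects)
    g = subjects["latent_g"].to_numpy()

    B = rng.standard_normal((n_rois, n_latent)) * 0.6
    ts = np.empty((n, n_frames, n_rois))
    motion = np.empty((n, n_frames, 6))
    # connectivity-to-g coupling: the resting-state comparator carries a
    # real but clearly weaker g signal than a demanding task contrast
    kappa = 0.35 * spec.gca_coupling
    for i in range(n):
        load = B.copy()
        load[:, 0] *= np.sqrt(max(0.05, 1.0 + kappa * g[i]))
        z = rng.standard_normal((n_frames, n_latent))
        ts[i] = z @ load.T + rng.standard_normal((n_frames, n_rois))

        steps = rng.normal(0.0, 0.02, size=(n_frames, 6))
        steps[:, 3:] *= 0.01           # rotations (radians) stay small
        spikes = rng.random(n_frames) < 0.04
        spikes[0] = False
        steps[spikes, :3] += rng.normal(0.0, 0.4, size=(int(spikes.sum()), 3))
        motion[i] = np.cumsum(steps, axis=0)
    return ts, motion
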