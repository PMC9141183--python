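"""The 249-dimension per-window feature battery.

For each 10 s, 15-channel window the default recipe computes:

* 4 time-domain statistics per channel (mean, standard deviation, mean
  absolute first difference, mean absolute lag-2 difference) ... 60
* alpha/beta/gamma band energies per channel (zero-phase Butterworth
  band-pass, sum of squared samples) .............................. 45
* beta/alpha energy ratios on four frontal channels ............... 4
* rational asymmetry (left/right band-power ratio) for the F3/F4 and
  AF3/AF4 pairs in the alpha and beta bands ....................... 4
* summed broadband power of the seven non-frontal channels ........ 1
* 9 nonlinear-dynamics features per channel on the broadband signal:
  sample entropy, approximate entropy, differential entropy, wavelet
  entropy, largest Lyapunov exponent, Higuchi fractal dimension,
  R/S Hurst exponent, Hjorth mobility and complexity .............. 135

for a total of 60 + 45 + 4 + 4 + 1 + 135 = 249 named features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from emofuse._kernels import apen_phi, rosenstein_divergence, sampen_counts
from emofuse.data_model import DEFAULT_CHANNELS, WindowedDataset

EPS = 1e-12          # denominator floor for all division guards
ENTROPY_CAP = math.log(1e6)  # cap for entropies that diverge (no template matches)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: ({self.low_hz}, {self.high_hz})")


ALPHA = BandDefinition("alpha", 8.0, 14.0)
BETA = BandDefinition("beta", 14.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 47.0)
DEFAULT_BANDS = (ALPHA, BETA, GAMMA)


@dataclass
class FeatureRecipe:
    """Fully determines the feature battery: channels, bands and parameters."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    # entropy parameters: embedding length m, tolerance r = r_factor * std(x)
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    # wavelet entropy
    wavelet: str = "db4"
    wavelet_levels: int = 5
    # Higuchi
    higuchi_kmax: int = 10
    # Hurst dyadic ladder: subseries lengths 16, 32, ..., n/2
    hurst_min_len: int = 16
    # Rosenstein Lyapunov
    lyap_dim: int = 10
    lyap_delay: int = 2
    lyap_fit_steps: int = 30
    # asymmetry pairs (left, right) evaluated in asymmetry_bands
    asymmetry_pairs: tuple[tuple[str, str], ...] = (("F3", "F4"), ("AF3", "AF4"))
    asymmetry_bands: tuple[str, ...] = ("alpha", "beta")
    # beta/alpha ratio channels
    ratio_channels: tuple[str, ...] = ("F3", "F4", "AF3", "AF4")
    # broadband power sum channel set (non-frontal electrodes)
    power_sum_channels: tuple[str, ...] = ("P7", "T7", "O1", "P8", "T8", "O2", "CZ")
    # Butterworth band-pass order (applied zero-phase, forward-backward)
    filter_order: int = 4
    # "equations" = mean/std/mean|diff1|/mean|lag-2 diff|;
    # "table" = mean/std/mean|diff1|/std(diff1)
    time_domain_variant: str = "equations"
    # which families to compute (mainly for reduced test recipes)
    families: tuple[str, ...] = (
        "time_domain", "band_energy", "band_ratio", "rasm", "power_sum", "nonlinear",
    )

    def feature_names(self) -> list[str]:
        """Deterministic, globally unique column names for this recipe."""
        names: list[str] = []
        if "time_domain" in self.families:
            if self.time_domain_variant == "table":
                stats_names = ("mean", "std", "diff1_mean", "diff1_std")
            else:
                stats_names = ("mean", "std", "diff1_mean", "diff2_mean")
            for ch in self.channels:
                names += [f"{ch}.{s}" for s in stats_names]
        if "band_energy" in self.families:
            for ch in self.channels:
                names += [f"{ch}.energy.{b.name}" for b in self.bands]
        if "band_ratio" in self.families:
            names += [f"{ch}.ratio.beta_alpha" for ch in self.ratio_channels]
        if "rasm" in self.families:
            for left, right in self.asymmetry_pairs:
                names += [f"rasm.{band}.{left}_{right}" for band in self.asymmetry_bands]
        if "power_sum" in self.families:
            names += ["power_sum.nonfrontal"]
        if "nonlinear" in self.families:
            nl = ("sampen", "apen", "de", "we", "lyap", "higuchi_fd",
                  "hurst", "hjorth_mobility", "hjorth_complexity")
            for ch in self.channels:
                names += [f"{ch}.{s}" for s in nl]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


@dataclass
class FeatureTable:
    """n_windows x n_features matrix with stable column names and provenance."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        if self.trial_ids is not None:
            df.insert(1, "trial_id", self.trial_ids)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path) -> None:
        """Binary-archive mirror of the CSV format (lossless float64)."""
        np.savez(
            path,
            values=self.values,
            feature_names=np.asarray(self.feature_names, dtype="U"),
            labels=self.labels,
            subject_ids=np.asarray(self.subject_ids, dtype="U"),
            trial_ids=(self.trial_ids if self.trial_ids is not None
                       else np.full(self.n_windows, -1)),
        )

    @staticmethod
    def from_npz(path) -> "FeatureTable":
        with np.load(path, allow_pickle=False) as archive:
            return FeatureTable(
                values=archive["values"],
                feature_names=list(archive["feature_names"]),
                labels=archive["labels"],
                subject_ids=archive["subject_ids"],
                trial_ids=archive["trial_ids"],
            )

    @staticmethod
    def from_csv(path) -> "FeatureTable":
        import pandas as pd

        df = pd.read_csv(path)
        meta = [c for c in ("subject_id", "trial_id", "label") if c in df.columns]
        feature_cols = [c for c in df.columns if c not in meta]
        return FeatureTable(
            values=df[feature_cols].to_numpy(dtype=np.float64),
            feature_names=feature_cols,
            labels=df["label"].to_numpy(dtype=np.int64),
            subject_ids=df["subject_id"].to_numpy(),
            trial_ids=df["trial_id"].to_numpy() if "trial_id" in df.columns else None,
        )


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def time_domain_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population std, mean |first difference|, mean |lag-2 difference|.

    The standard deviation divides by T (population form), the first
    difference mean by T-1 and the lag-2 difference mean by T-2.
    """
    x = np.asarray(x, dtype=np.float64)
    t = x.shape[0]
    if t < 3:
        raise ValueError("need at least 3 samples")
    mu = x.mean()
    sigma = float(np.sqrt(((x - mu) ** 2).mean()))
    d1 = float(np.abs(x[1:] - x[:-1]).mean())
    d2 = float(np.abs(x[2:] - x[:-2]).mean())
    return float(mu), sigma, d1, d2


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def _butter_sos(band: BandDefinition, fs: float, order: int):
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.high_hz} >= Nyquist {nyq}")
    return sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                      fs=fs, output="sos")


def bandpass(x: np.ndarray, band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass; length preserved."""
    sos = _butter_sos(band, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def band_energy(x: np.ndarray, band: BandDefinition, fs: float, order: int = 4) -> float:
    """Band energy = sum of squared samples of the band-passed window."""
    y = bandpass(x, band, fs, order)
    return float(np.sum(y * y))


def rasm(p_left: float, p_right: float) -> float:
    """Rational asymmetry: left-hemisphere power over right-hemisphere power."""
    return float(p_left) / max(float(p_right), EPS)


def band_ratio(x: np.ndarray, fs: float, order: int = 4,
               num: BandDefinition = BETA, den: BandDefinition = ALPHA) -> float:
    """Energy ratio between two bands on one channel (default beta/alpha)."""
    return band_energy(x, num, fs, order) / max(band_energy(x, den, fs, order), EPS)


def power_sum(windows: np.ndarray) -> float:
    """Sum over channels of the mean squared broadband signal."""
    windows = np.asarray(windows, dtype=np.float64)
    return float((windows ** 2).mean(axis=-1).sum())


# ---------------------------------------------------------------------------
# Nonlinear dynamics
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B), self-matches excluded, Chebyshev distance.

    ``r`` defaults to 0.2 x population std of the window. Zero matches at
    either length are guarded by capping at ln(1e6).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.shape[0] <= m + 1:
        raise ValueError("series too short for the requested m")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        return 0.0  # constant series: every template matches
    a, b = sampen_counts(x, m, float(r))
    if b == 0 or a == 0:
        return ENTROPY_CAP
    return float(min(-math.log(a / b), ENTROPY_CAP))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r), self-matches included."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.shape[0] <= m + 1:
        raise ValueError("series too short for the requested m")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        return 0.0
    return float(min(apen_phi(x, m, float(r)) - apen_phi(x, m + 1, float(r)),
                     ENTROPY_CAP))


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian closed form 0.5*ln(2*pi*e*sigma^2), sample variance, nats."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    var = max(float(np.var(x, ddof=1)), EPS)
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def relative_energy_entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p ln p of a relative-energy distribution."""
    p = np.asarray(p, dtype=np.float64)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def wavelet_entropy(x: np.ndarray, wavelet: str = "db4", levels: int = 5) -> float:
    """Shannon entropy of relative wavelet sub-band energies.

    A ``levels``-level DWT yields ``levels + 1`` coefficient sets; their
    energies are normalized to a distribution and its entropy returned.
    Zero total energy maps to 0 by convention.
    """
    coeffs = pywt.wavedec(np.asarray(x, dtype=np.float64), wavelet, level=levels)
    energies = np.array([float(np.sum(c * c)) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        return 0.0
    return relative_energy_entropy(energies / total)


def lyapunov_max(x: np.ndarray, dim: int = 10, delay: int = 2,
                 fit_steps: int = 30, theiler: int | None = None,
                 dt: float = 1.0) -> float:
    """Largest Lyapunov exponent via the Rosenstein small-data method.

    Time-delay embedding, nearest neighbors outside a Theiler window, then a
    least-squares slope of the mean log-divergence curve over the first
    ``fit_steps`` iterations. Units: nats per sample divided by ``dt``.
    Constant input returns 0.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.shape[0] < 200:
        raise ValueError("need at least 200 samples")
    if float(np.std(x)) < EPS:
        return 0.0
    if theiler is None:
        theiler = delay
    curve = rosenstein_divergence(x, dim, delay, theiler, fit_steps)
    steps = np.arange(curve.shape[0], dtype=np.float64)
    ok = np.isfinite(curve)
    if ok.sum() < 2:
        return 0.0
    slope, _, _, _, _ = stats.linregress(steps[ok], curve[ok])
    return float(slope) / dt


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension: slope of ln L(k) vs ln(1/k), clipped to [1, 2]."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 2 * k_max:
        raise ValueError("series too short for the requested k_max")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_vals = np.arange(1, k_max + 1, dtype=np.float64)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0
    slope, _, _, _, _ = stats.linregress(np.log(1.0 / k_vals[valid]), np.log(lk[valid]))
    return float(np.clip(slope, 1.0, 2.0))


def hurst_rs(x: np.ndarray, min_len: int = 16) -> float:
    """R/S Hurst exponent over a dyadic ladder of subseries lengths.

    For each length L in {min_len, 2*min_len, ..., n/2} the series is split
    into floor(n/L) contiguous blocks; each block's rescaled range R/S is the
    range of its mean-adjusted cumulative sum over its standard deviation.
    H is the regression slope of log mean(R/S) against log L, clipped to
    [0, 1]. A constant series returns 0.5 (no information either way).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 4 * min_len:
        raise ValueError("series too short for the R/S ladder")
    if float(np.std(x)) < EPS:
        return 0.5
    sizes = []
    size = min_len
    while size <= n // 2:
        sizes.append(size)
        size *= 2
    log_l, log_rs = [], []
    for size in sizes:
        g = n // size
        rs_vals = []
        for i in range(g):
            block = x[i * size:(i + 1) * size]
            s = float(np.std(block))
            if s < EPS:
                continue
            dev = np.cumsum(block - block.mean())
            rs_vals.append((dev.max() - dev.min()) / s)
        if rs_vals:
            log_l.append(math.log(size))
            log_rs.append(math.log(max(np.mean(rs_vals), EPS)))
    if len(log_l) < 2:
        return 0.5
    slope, _, _, _, _ = stats.linregress(log_l, log_rs)
    return float(np.clip(slope, 0.0, 1.0))


def hjorth(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity from first-difference derivatives."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    var_x = float(np.var(x))
    if var_x < EPS:
        return 0.0, 0.0
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    mobility = math.sqrt(var_dx / var_x)
    var_ddx = float(np.var(np.diff(dx)))
    if var_dx < EPS:
        return mobility, 0.0
    mobility_dx = math.sqrt(var_ddx / var_dx)
    return mobility, mobility_dx / max(mobility, EPS)


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

def _window_features(win: np.ndarray, fs: float, recipe: FeatureRecipe,
                     ch_index: dict[str, int]) -> np.ndarray:
    out: list[float] = []
    order = recipe.filter_order

    band_by_name = {b.name: b for b in recipe.bands}
    # cache band-passed signals per (channel, band) for energy/ratio/rasm reuse
    energy_cache: dict[tuple[str, str], float] = {}

    def energy(ch: str, band_name: str) -> float:
        key = (ch, band_name)
        if key not in energy_cache:
            energy_cache[key] = band_energy(
                win[ch_index[ch]], band_by_name[band_name], fs, order
            )
        return energy_cache[key]

    if "time_domain" in recipe.families:
        for ch in recipe.channels:
            x = win[ch_index[ch]]
            mu, sigma, d1, d2 = time_domain_stats(x)
            if recipe.time_domain_variant == "table":
                out += [mu, sigma, d1, float(np.std(np.diff(x)))]
            else:
                out += [mu, sigma, d1, d2]
    if "band_energy" in recipe.families:
        for ch in recipe.channels:
            out += [energy(ch, b.name) for b in recipe.bands]
    if "band_ratio" in recipe.families:
        for ch in recipe.ratio_channels:
            out.append(energy(ch, "beta") / max(energy(ch, "alpha"), EPS))
    if "rasm" in recipe.families:
        for left, right in recipe.asymmetry_pairs:
            for band in recipe.asymmetry_bands:
                out.append(rasm(energy(left, band), energy(right, band)))
    if "power_sum" in recipe.families:
        idx = [ch_index[c] for c in recipe.power_sum_channels]
        out.append(power_sum(win[idx]))
    if "nonlinear" in recipe.families:
        for ch in recipe.channels:
            x = win[ch_index[ch]]
            r = recipe.sampen_r_factor * float(np.std(x))
            out.append(sample_entropy(x, recipe.sampen_m, r))
            out.append(approximate_entropy(x, recipe.sampen_m, r))
            out.append(differential_entropy(x))
            out.append(wavelet_entropy(x, recipe.wavelet, recipe.wavelet_levels))
            out.append(lyapunov_max(x, recipe.lyap_dim, recipe.lyap_delay,
                                    recipe.lyap_fit_steps))
            out.append(higuchi_fd(x, recipe.higuchi_kmax))
            out.append(hurst_rs(x, recipe.hurst_min_len))
            mob, comp = hjorth(x)
            out += [mob, comp]
    return np.asarray(out, dtype=np.float64)


def extract_all(dataset: WindowedDataset,
                recipe: FeatureRecipe | None = None) -> FeatureTable:
    """Compute the full feature battery for every window in the dataset.

    Column order is fixed by :meth:`FeatureRecipe.feature_names`; the default
    recipe on 15 channels yields exactly 249 columns. Any non-finite value
    produced by a degenerate window is replaced by 0 after the division and
    entropy guards.
    """
    recipe = recipe or FeatureRecipe()
    available = {c.upper() for c in dataset.channel_names}
    lookup = {c.upper(): i for i, c in enumerate(dataset.channel_names)}
    needed = set(recipe.channels)
    if "band_ratio" in recipe.families:
        needed |= set(recipe.ratio_channels)
    if "power_sum" in recipe.families:
        needed |= set(recipe.power_sum_channels)
    if "rasm" in recipe.families:
        needed |= {c for pair in recipe.asymmetry_pairs for c in pair}
    missing = [c for c in needed if c.upper() not in available]
    if missing:
        raise KeyError(f"recipe channels missing from dataset: {sorted(missing)}")
    ch_index = {c: lookup[c.upper()] for c in needed}
    names = recipe.feature_names()
    values = np.empty((dataset.n_windows, len(names)), dtype=np.float64)
    for i in range(dataset.n_windows):
        values[i] = _window_features(dataset.windows[i], dataset.sampling_rate,
                                     recipe, ch_index)
    values[~np.isfinite(values)] = 0.0
    return FeatureTable(
        values=values,
        feature_names=names,
        labels=np.asarray(dataset.labels),
        subject_ids=np.asarray(dataset.subject_ids),
        trial_ids=np.asarray(dataset.trial_ids),
    )
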