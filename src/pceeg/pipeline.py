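"""End-to-end orchestration: simulate -> preprocess -> TFR -> statistics -> report.

The test matrix mirrors the analysis design: stimulus-locked data are tested
for INT, EXP and PE in both frequency bands (six analyses); cue-locked data
are tested for EXP only, again in both bands (two analyses).  Everything is
reproducible from the three seeds in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import design, spectral, stats, synth

__all__ = [
    "DesignConfig", "SynthConfig", "SpectralConfig", "StatsConfig", "RunConfig",
    "AnalysisResult", "ReportBundle", "partial_out", "run_pipeline",
]

log = logging.getLogger("pceeg")


@dataclass
class DesignConfig:
    n_per_cue: int = 50
    n_blocks: int = 4
    catch_per_block: int = 4
    seed: int = 101


@dataclass
class SynthConfig:
    n_subjects: int = 12
    montage_rows: int = 4
    montage_cols: int = 4
    srate: float = 250.0
    epoch_window_ms: tuple[float, float] = (-2750.0, 2200.0)
    seed: int = 202
    effects: dict = field(default_factory=dict)   # EffectSpec overrides
    rating_beta0: float = 2.5
    rating_beta_int: float = 0.6
    rating_beta_pe: float = 0.25
    rating_sigma: float = 0.5


@dataclass
class SpectralConfig:
    low_freqs: tuple[int, int] = (1, 30)
    high_freqs: tuple[int, int] = (31, 100)
    low_window_ms: float = 300.0
    high_window_ms: float = 200.0
    step_ms: float = 50.0
    smoothing_hz: float = 15.0
    cue_baseline_ms: tuple[float, float] = spectral.CUE_BASELINE_MS
    stim_baseline_ms: tuple[float, float] = spectral.stimulus_locked_baseline()
    stim_test_window_ms: tuple[float, float] = (0.0, 2000.0)
    cue_test_window_ms: tuple[float, float] = (0.0, 1500.0)


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 303
    add_one: bool = False
    #: "split" judges each sign tail at alpha/2 (two-sided control at alpha);
    #: "per_tail" evaluates each tail at the full alpha
    tail_mode: str = "split"
    #: optional subset of (lock, band, factor) analyses; None = full matrix
    tests: tuple[tuple[str, str, str], ...] | None = None


@dataclass
class RunConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self):
        lo = self.spectral.low_freqs
        hi = self.spectral.high_freqs
        if not (1 <= lo[0] <= lo[1] <= 30):
            raise ValueError("low band must lie within [1, 30] Hz")
        if not (31 <= hi[0] <= hi[1] <= 100):
            raise ValueError("high band must lie within [31, 100] Hz")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        dd = dict(d.get("design", {}))
        sd = dict(d.get("synth", {}))
        pd_ = dict(d.get("spectral", {}))
        td = dict(d.get("stats", {}))
        for key in ("epoch_window_ms",):
            if key in sd:
                sd[key] = tup(sd[key])
        for key in ("low_freqs", "high_freqs", "cue_baseline_ms", "stim_baseline_ms",
                    "stim_test_window_ms", "cue_test_window_ms"):
            if key in pd_:
                pd_[key] = tup(pd_[key])
        if td.get("tests") is not None:
            td["tests"] = tuple(tuple(t) for t in td["tests"])
        return cls(
            design=DesignConfig(**dd),
            synth=SynthConfig(**sd),
            spectral=SpectralConfig(**pd_),
            stats=StatsConfig(**td),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def partial_out(cell_values: np.ndarray, target_factor: str) -> np.ndarray:
    """Remove the other two factors' linear components, for display.

    Per subject, the nine cell values are regressed on an intercept and the
    two non-target factor code vectors; the residuals plus the subject's
    grand mean are returned.  The target factor's own component is untouched
    (INT and EXP are orthogonal to each other and to PE under equal cell
    weighting).
    """
    if target_factor not in design.FACTORS:
        raise ValueError(f"unknown factor {target_factor!r}")
    values = np.asarray(cell_values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 9:
        raise ValueError("cell_values must be subjects x 9")
    nuisance = [f for f in design.FACTORS if f != target_factor]
    cells = design.build_condition_grid()
    attr = {"INT": "int_code", "EXP": "exp_code", "PE": "pe_code"}
    X = np.column_stack(
        [np.ones(9)] + [np.array([getattr(c, attr[f]) for c in cells], dtype=float)
                        for f in nuisance]
    )
    proj = X @ np.linalg.pinv(X)  # 9 x 9 hat matrix
    fitted = values @ proj.T
    return values - fitted + values.mean(axis=1, keepdims=True)


@dataclass
class AnalysisResult:
    factor: str
    band: str
    lock: str
    result: stats.PermutationResult
    posthoc: list[stats.PostHocTable]
    partial_level_means: np.ndarray  # subjects x 3, other factors partialled out
    cell_values: np.ndarray          # subjects x 9 cluster-averaged values (top cluster)


@dataclass
class ReportBundle:
    config: RunConfig
    analyses: list[AnalysisResult]
    ratings: dict

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        out = {"analyses": [], "ratings": {}}
        for a in self.analyses:
            top = a.result.clusters[0] if a.result.clusters else None
            out["analyses"].append(
                {
                    "factor": a.factor,
                    "band": a.band,
                    "lock": a.lock,
                    "threshold": a.result.threshold,
                    "n_perm": a.result.n_perm,
                    "seed": a.result.seed,
                    "n_clusters": len(a.result.clusters),
                    "n_significant": len(a.result.significant()),
                    "top_cluster": None if top is None else {
                        "sign": top.sign, "value": top.value, "p": top.p,
                        "n_members": int(len(top.members)),
                    },
                }
            )
        for factor, r in self.ratings.items():
            out["ratings"][factor] = {"F": r.F, "p": r.p, "df": list(r.df)}
        return out

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=1)


def _subject_seeds(root_seed: int, n_subjects: int) -> list[tuple[int, int, int]]:
    """Per-subject (schedule, eeg, rating) integer seeds below 2**31."""
    out = []
    for i in range(n_subjects):
        state = np.random.SeedSequence([root_seed, i]).generate_state(3)
        out.append(tuple(int(s % (2 ** 31)) for s in state))
    return out


def simulate_study(config: RunConfig):
    """Simulate all subjects: schedules, preprocessed epochs and ratings."""
    montage = synth.make_montage(config.synth.montage_rows, config.synth.montage_cols)
    effects = synth.EffectSpec(**config.synth.effects)
    subjects = []
    for i, (s_sched, s_eeg, s_rate) in enumerate(
        _subject_seeds(config.synth.seed, config.synth.n_subjects)
    ):
        schedule = design.build_trial_schedule(
            config.design.n_per_cue, config.design.n_blocks,
            config.design.catch_per_block, seed=(config.design.seed + i) % (2 ** 31),
        )
        epochs = synth.simulate_subject_eeg(
            schedule, montage, effects, srate=config.synth.srate,
            epoch_window_ms=config.synth.epoch_window_ms, seed=s_eeg,
            subject_id=f"s{i:02d}",
        )
        ratings = synth.simulate_ratings(
            schedule, config.synth.rating_beta0, config.synth.rating_beta_int,
            config.synth.rating_beta_pe, config.synth.rating_sigma, seed=s_rate,
        )
        subjects.append((schedule, epochs, ratings))
    return montage, subjects


def preprocess(epochs: synth.EpochsSet) -> synth.EpochsSet:
    """Detrend, 1-100 Hz band-pass, common-average re-reference."""
    e = spectral.epoch_and_detrend(epochs)
    e = spectral.bandpass(e, 1.0, min(100.0, e.srate / 2.0 - 1.0))
    return spectral.rereference_common_average(e)


def _band_freqs(band_range: tuple[int, int]) -> np.ndarray:
    return np.arange(band_range[0], band_range[1] + 1)


def compute_condition_tfrs(config: RunConfig, montage, subjects,
                           needed: set[tuple[str, str]] | None = None) -> dict:
    """Baselined condition-average TFRs per (lock, band), stacked over subjects.

    ``needed`` restricts which (lock, band) combinations are computed.
    Window centers are only evaluated inside the baseline and test windows -
    everything the statistics consume - which keeps the sliding transforms
    proportional to the analyzed time range.
    """
    sp = config.spectral
    if needed is None:
        needed = {(lock, band) for lock in ("stimulus", "cue") for band in ("low", "high")}
    collected: dict[tuple[str, str], list] = {key: [] for key in needed}
    windows = {
        "stimulus": [sp.stim_baseline_ms, sp.stim_test_window_ms],
        "cue": [sp.cue_baseline_ms, sp.cue_test_window_ms],
    }
    for schedule, epochs, _ in subjects:
        clean = preprocess(epochs)
        locked = {"stimulus": clean}
        if any(lock == "cue" for lock, _ in needed):
            locked["cue"] = spectral.timelock(clean, "cue", schedule)
        for lock, band in needed:
            eset = locked[lock]
            if band == "low":
                trial_tfr = spectral.tfr_hanning(
                    eset, _band_freqs(sp.low_freqs), sp.low_window_ms, sp.step_ms,
                    center_windows_ms=windows[lock],
                )
            else:
                trial_tfr = spectral.tfr_multitaper(
                    eset, _band_freqs(sp.high_freqs), sp.high_window_ms, sp.step_ms,
                    sp.smoothing_hz, center_windows_ms=windows[lock],
                )
            collected[(lock, band)].append(
                spectral.average_by_condition(trial_tfr, schedule)
            )

    out = {}
    for (lock, band), tfrs in collected.items():
        stacked = spectral.stack_subjects(tfrs)
        window = sp.stim_baseline_ms if lock == "stimulus" else sp.cue_baseline_ms
        out[(lock, band)] = spectral.zbaseline(stacked, window)
    return out


#: the analysis matrix: stimulus-locked tested for all factors, cue-locked for EXP
TEST_MATRIX = (
    [("stimulus", band, factor) for factor in design.FACTORS for band in ("low", "high")]
    + [("cue", band, "EXP") for band in ("low", "high")]
)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full simulate -> TFR -> cluster-statistics pipeline."""
    log.info("simulate: %d subjects, %d trials/cue, seed %d",
             config.synth.n_subjects, config.design.n_per_cue, config.synth.seed)
    montage, subjects = simulate_study(config)

    matrix = (list(config.stats.tests) if config.stats.tests is not None
              else list(TEST_MATRIX))
    log.info("tfr: low %s Hz (Hanning %g ms), high %s Hz (multitaper %g ms, +-%g Hz)",
             config.spectral.low_freqs, config.spectral.low_window_ms,
             config.spectral.high_freqs, config.spectral.high_window_ms,
             config.spectral.smoothing_hz)
    tfrs = compute_condition_tfrs(
        config, montage, subjects, needed={(lock, band) for lock, band, _ in matrix}
    )

    analyses = []
    for k, (lock, band, factor) in enumerate(matrix):
        tfr = tfrs[(lock, band)]
        window = (config.spectral.stim_test_window_ms if lock == "stimulus"
                  else config.spectral.cue_test_window_ms)
        sliced = tfr.time_slice(window)
        log.info("test: factor %s, band %s, lock %s, %d permutations",
                 factor, band, lock, config.stats.n_perm)
        result = stats.permutation_test(
            sliced.power, factor, montage,
            n_perm=config.stats.n_perm, alpha=config.stats.alpha,
            seed=(config.stats.seed + k) % (2 ** 31), add_one=config.stats.add_one,
            tail_mode=config.stats.tail_mode,
        )
        posthoc = [
            stats.posthoc_pairwise(c, sliced.power, factor)
            for c in result.significant()
        ]
        if result.clusters:
            top = result.clusters[0]
            ch, fr, ti = top.members.T
            cell_vals = sliced.power[:, :, ch, fr, ti].mean(axis=2)
        else:
            cell_vals = sliced.power.mean(axis=(2, 3, 4))
        adjusted = partial_out(cell_vals, factor)
        level_means, _ = stats.factor_level_means(adjusted, factor)
        analyses.append(
            AnalysisResult(factor, band, lock, result, posthoc, level_means, cell_vals)
        )

    ratings_cells = np.stack(
        [_ratings_cell_means(ratings) for _, _, ratings in subjects], axis=0
    )
    ratings_results = stats.ratings_tests(ratings_cells)

    return ReportBundle(config=config, analyses=analyses, ratings=ratings_results)


def _ratings_cell_means(ratings) -> np.ndarray:
    """Mean rating per canonical condition cell for one subject."""
    cells = design.build_condition_grid()
    out = np.empty(9)
    cue = ratings["cue_intensity"].to_numpy()
    stim = ratings["stim_intensity"].to_numpy()
    vals = ratings["rating"].to_numpy(dtype=float)
    for i, cell in enumerate(cells):
        sel = (cue == cell.cue_intensity) & (stim == cell.stim_intensity)
        if not sel.any():
            raise ValueError(
                f"no ratings in cell (cue={cell.cue_intensity}, stim={cell.stim_intensity})"
            )
        out[i] = vals[sel].mean()
    return out
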