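"""End-to-end orchestration: simulate -> preprocess -> decode -> statistics.

``run_experiment`` executes the full comparison matrix on synthetic sessions:
pooled direction, pooled cue, within-cue direction, cue within direction,
static near/far, and cross-trained decoding both ways — per-participant
decoding timecourses, group cluster statistics, CSV/JSON artifacts and a
reproducibility manifest.  Epochs travel in an HDF5 container with a JSON
sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluststats import ClusterResult, bonferroni_pointwise, cluster_test
from .decode import (DecodeConfig, DecodingTimecourse, cross_decode_timecourse,
                     decode_timecourse, pool_conditions)
from .errors import ConfigurationError, IOFormatError
from .preprocess import PreprocConfig, preprocess_epochs
from .resample import build_pool
from .synth import (STATIC_CONDITIONS, EpochSet, SessionSpec,
                    default_static_components, generate_participant)

__all__ = [
    "SCHEMA_VERSION",
    "StatsConfig",
    "ExperimentConfig",
    "ComparisonResult",
    "ExperimentResult",
    "COMPARISONS",
    "write_epochs",
    "read_epochs",
    "run_experiment",
    "summarize",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "middecode-epochs-1"


# ---------------------------------------------------------------------------
# epoch container


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write one participant's epochs to HDF5 (+ JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["participant_id"] = epochs.participant_id
        f.attrs["rate_hz"] = float(epochs.rate_hz)
        f.create_dataset("epochs", data=epochs.data.astype("<f8"))
        f.create_dataset("labels",
                         data=np.asarray(epochs.labels, dtype=object),
                         dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("time_ms", data=epochs.times_ms.astype("<f8"))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": epochs.participant_id,
        "rate_hz": float(epochs.rate_hz),
        "n_epochs": int(epochs.n_epochs),
        "n_channels": int(epochs.n_channels),
        "n_times": int(epochs.times_ms.size),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Round-trip-lossless reader for the epoch container."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise IOFormatError(
                    f"{path}: schema version {version!r} != {SCHEMA_VERSION!r}"
                )
            labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                               for s in f["labels"][()]])
            return EpochSet(
                participant_id=str(f.attrs["participant_id"]),
                data=f["epochs"][()],
                labels=labels,
                times_ms=f["time_ms"][()],
                rate_hz=float(f.attrs["rate_hz"]),
            )
    except OSError as exc:
        raise IOFormatError(f"{path}: not a readable epoch container ({exc})") from exc


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StatsConfig:
    alpha_forming: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 5000
    tail: str = "greater"


# comparison registry: name -> (session key, kind, arguments)
COMPARISONS: dict[str, dict] = {
    "pooled_direction": {"session": "mid", "kind": "pooled",
                         "scheme": "direction_pooled", "pair": ("AWAY", "TOWARD")},
    "pooled_cue": {"session": "mid", "kind": "pooled",
                   "scheme": "cue_pooled", "pair": ("CD", "IOVD")},
    "cd_direction": {"session": "mid", "kind": "pair",
                     "pair": ("CD_AWAY", "CD_TOWARD")},
    "iovd_direction": {"session": "mid", "kind": "pair",
                       "pair": ("IOVD_AWAY", "IOVD_TOWARD")},
    "cue_within_toward": {"session": "mid", "kind": "pair",
                          "pair": ("CD_TOWARD", "IOVD_TOWARD")},
    "cue_within_away": {"session": "mid", "kind": "pair",
                        "pair": ("CD_AWAY", "IOVD_AWAY")},
    "static_near_far": {"session": "static", "kind": "pair",
                        "pair": ("STATIC_FAR", "STATIC_NEAR")},
    "cross_cd_to_iovd": {"session": "mid", "kind": "cross",
                         "train": ("CD_AWAY", "CD_TOWARD"),
                         "test": ("IOVD_AWAY", "IOVD_TOWARD")},
    "cross_iovd_to_cd": {"session": "mid", "kind": "cross",
                         "train": ("IOVD_AWAY", "IOVD_TOWARD"),
                         "test": ("CD_AWAY", "CD_TOWARD")},
}


def default_static_session(base: SessionSpec) -> SessionSpec:
    """Static-disparity control session derived from the main session spec
    (3 blocks of 210 retained trials over 2 conditions)."""
    return dataclasses.replace(
        base,
        n_blocks=max(1, base.n_blocks // 2),
        condition_set=STATIC_CONDITIONS,
        components=default_static_components(base.n_channels),
        master_seed=base.master_seed + 1_000_003,
    )


@dataclass
class ExperimentConfig:
    session: SessionSpec = field(default_factory=SessionSpec)
    static_session: Optional[SessionSpec] = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    comparisons: tuple[str, ...] = tuple(COMPARISONS)
    out_dir: Optional[str] = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.comparisons) - set(COMPARISONS)
        if unknown:
            raise ConfigurationError(f"unknown comparison(s): {sorted(unknown)}")
        self.session = dataclasses.replace(self.session, master_seed=self.master_seed)
        needs_static = any(COMPARISONS[c]["session"] == "static"
                           for c in self.comparisons)
        if needs_static and self.static_session is None:
            self.static_session = default_static_session(self.session)


# ---------------------------------------------------------------------------
# run


@dataclass
class ComparisonResult:
    name: str
    timecourses: list[DecodingTimecourse]
    matrix: np.ndarray  # participants x timepoints
    times_ms: np.ndarray
    clusters: ClusterResult
    bonferroni: np.ndarray


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    comparisons: dict[str, ComparisonResult]
    manifest: dict


def _decode_seed(master_seed: int, participant: int, comparison: str) -> int:
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(0xDEC0, participant, zlib.crc32(comparison.encode())),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _run_comparison(name: str, pool, cfg: ExperimentConfig, participant: int
                    ) -> DecodingTimecourse:
    spec = COMPARISONS[name]
    dec_cfg = dataclasses.replace(
        cfg.decode, base_seed=_decode_seed(cfg.master_seed, participant, name)
    )
    if spec["kind"] == "pair":
        return decode_timecourse(pool, spec["pair"], dec_cfg, comparison=name)
    if spec["kind"] == "pooled":
        merged = pool_conditions(pool, spec["scheme"])
        return decode_timecourse(merged, spec["pair"], dec_cfg, comparison=name)
    if spec["kind"] == "cross":
        return cross_decode_timecourse(pool, spec["train"], spec["test"], dec_cfg,
                                       comparison=name)
    raise ConfigurationError(f"unknown comparison kind {spec['kind']!r}")


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute every configured comparison and the group statistics."""
    sessions: dict[str, SessionSpec] = {"mid": cfg.session}
    if cfg.static_session is not None:
        sessions["static"] = cfg.static_session
    by_session: dict[str, list[str]] = {}
    for name in cfg.comparisons:
        by_session.setdefault(COMPARISONS[name]["session"], []).append(name)

    collected: dict[str, list[DecodingTimecourse]] = {c: [] for c in cfg.comparisons}
    times: dict[str, np.ndarray] = {}
    for skey, names in by_session.items():
        spec = sessions.get(skey)
        if spec is None:
            raise ConfigurationError(f"no session spec for {skey!r} comparisons")
        for p in range(spec.n_participants):
            logger.info("simulating + preprocessing %s participant %d", skey, p)
            epochs = preprocess_epochs(generate_participant(spec, p), cfg.preproc)
            pool = build_pool(epochs)
            for name in names:
                logger.info("decoding %s for participant %d", name, p)
                tc = _run_comparison(name, pool, cfg, p)
                collected[name].append(tc)
                times[name] = tc.times_ms

    results: dict[str, ComparisonResult] = {}
    for name in cfg.comparisons:
        tcs = collected[name]
        mat = np.stack([tc.accuracy for tc in tcs])
        st = cfg.stats
        clusters = cluster_test(
            mat, alpha_forming=st.alpha_forming, cluster_alpha=st.cluster_alpha,
            n_permutations=st.n_permutations, tail=st.tail,
            seed=_decode_seed(cfg.master_seed, 0xC1, name),
        )
        results[name] = ComparisonResult(
            name=name, timecourses=tcs, matrix=mat, times_ms=times[name],
            clusters=clusters, bonferroni=bonferroni_pointwise(
                mat, alpha=st.cluster_alpha, tail=st.tail),
        )

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "comparisons": list(cfg.comparisons),
        "n_participants": {k: s.n_participants for k, s in sessions.items()},
        "decode": {"n_iterations": cfg.decode.n_iterations,
                   "n_draw": cfg.decode.n_draw, "n_means": cfg.decode.n_means,
                   "C": cfg.decode.C, "fold_scheme": cfg.decode.fold_scheme},
        "stats": dataclasses.asdict(cfg.stats),
    }
    result = ExperimentResult(config=cfg, comparisons=results, manifest=manifest)
    if cfg.out_dir is not None:
        write_results(result, cfg.out_dir)
    return result


# ---------------------------------------------------------------------------
# artifacts


def write_results(result: ExperimentResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    clus_rows = []
    for name, comp in result.comparisons.items():
        frames.extend(tc.to_frame() for tc in comp.timecourses)
        for c in comp.clusters.clusters:
            clus_rows.append({
                "comparison": name,
                "start_ms": comp.times_ms[c.start],
                "end_ms": comp.times_ms[c.end],
                "mass": c.mass,
                "p": c.p_value,
                "significant": bool(c.significant),
            })
    pd.concat(frames, ignore_index=True).to_csv(out / "decoding.csv", index=False)
    cols = ["comparison", "start_ms", "end_ms", "mass", "p", "significant"]
    pd.DataFrame(clus_rows, columns=cols).to_csv(out / "clusters.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    summarize(result).to_csv(out / "summary.csv", index=False)
    return out


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Per comparison: peak accuracy/latency and significant-cluster extents."""
    rows = []
    for name, comp in result.comparisons.items():
        group_mean = comp.matrix.mean(axis=0)
        peaks = np.flatnonzero(group_mean == group_mean.max())
        if peaks.size > 1:
            logger.info("%s: %d tied peak timepoints; reporting the earliest",
                        name, peaks.size)
        peak_idx = int(peaks[0])
        sig = comp.clusters.significant_clusters
        extents = ";".join(
            f"{comp.times_ms[c.start]:.0f}-{comp.times_ms[c.end]:.0f}" for c in sig
        )
        rows.append({
            "comparison": name,
            "peak_accuracy": float(group_mean[peak_idx]),
            "peak_latency_ms": float(comp.times_ms[peak_idx]),
            "n_significant_clusters": len(sig),
            "significant_extents_ms": extents,
            "first_onset_ms": (float(comp.times_ms[sig[0].start]) if sig else np.nan),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# yaml config round-trip (scalar fields; component topographies are rebuilt
# from the deterministic defaults unless given explicitly)


def config_to_yaml(cfg: ExperimentConfig, path: str | Path) -> None:
    d = {
        "master_seed": cfg.master_seed,
        "comparisons": list(cfg.comparisons),
        "session": {
            "n_participants": cfg.session.n_participants,
            "n_blocks": cfg.session.n_blocks,
            "trials_retained_per_block": cfg.session.trials_retained_per_block,
            "raw_rate_hz": cfg.session.raw_rate_hz,
            "n_channels": cfg.session.n_channels,
            "noise": dataclasses.asdict(cfg.session.noise),
        },
        "preproc": dataclasses.asdict(cfg.preproc),
        "decode": dataclasses.asdict(cfg.decode),
        "stats": dataclasses.asdict(cfg.stats),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    session_kwargs = dict(d.get("session", {}))
    if "noise" in session_kwargs:
        from .synth import NoiseSpec

        session_kwargs["noise"] = NoiseSpec(**session_kwargs["noise"])
    return ExperimentConfig(
        session=SessionSpec(**session_kwargs),
        preproc=PreprocConfig(**d.get("preproc", {})),
        decode=DecodeConfig(**d.get("decode", {})),
        stats=StatsConfig(**d.get("stats", {})),
        comparisons=tuple(d.get("comparisons", tuple(COMPARISONS))),
        master_seed=int(d.get("master_seed", 0)),
    )
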