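"""Synthetic lifelog studies with known embedded neural effects.

No raw study data are deposited for this kind of experiment, so every stage
of the pipeline is exercised on generated data whose ground truth is known.
A generated study emulates the real design: 9 participants each contribute
120 events spanning ~30 days within ~30 km, drawn from a handful of latent
daily-life contexts (e.g. a library-study-alone context).  Each context has
a home GPS cluster, a time-of-day profile, a tag-probability profile (which
induces positive NPMI between within-context tags), and an image-feature
prototype (which makes temporal and visual neighborhoods congruent, so the
common neighbor ratio is informative).  Vividness is Bernoulli(0.47) among
remembered events, reminiscence success Bernoulli(0.63).

Neural data are built mechanistically rather than from the regression
equation: every tag owns a random spatial prototype over a designated
signal region, and the pattern evoked by a trial is the sum of its tags'
prototypes, scaled by 1 for vivid trials and by an attenuation a < 1
otherwise, plus isotropic Gaussian noise (pure noise outside the region).
Sharing tags therefore raises pattern correlation, so neural distance grows
with Hamming distance inside the region — more steeply for vivid pairs,
which is exactly a positive Hamm coefficient with a negative Hamm x Vivid
interaction.  Attenuation (rather than an additive vividness effect) is the
mechanism because it yields that signature without hand-coding any linear
coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pair_builder import EventRecord, PairFilterConfig, build_pairs, events_to_csv
from .searchlight_rsa import (
    BetaVolume,
    ModelSpec,
    SubjectSearchlight,
    sphere_offsets,
)
from .tag_semantics import TagVocabulary, load_vocabulary
from .visual_features import FeatureVector, features_to_csv

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Study",
    "simulate_events",
    "simulate_betas",
    "simulate_study",
    "build_study_pairs",
    "study_searchlights",
    "write_study",
]

_EPOCH0 = 1_600_000_000.0  # arbitrary fixed epoch origin for clock times
_DEG_PER_KM_LAT = 1.0 / 111.195  # mean-radius great-circle degrees per km


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generator settings.

    The defaults are the study conditions themselves: 9 participants x 120
    events over ~30 days within <=30 km, ~47% vivid responses among the ~63%
    remembered, 2.5 mm isotropic voxels.  ``seed`` is mandatory; every
    random stream derives from it deterministically.
    """

    seed: int
    n_participants: int = 9
    n_events: int = 120
    duration_days: int = 30
    extent_km: float = 25.0
    p_vivid: float = 0.47
    p_remembered: float = 0.63
    n_contexts: int = 6
    tags_per_context: int = 5
    n_common_tags: int = 8
    p_core_tag: float = 0.8
    p_common_tag: float = 0.5
    p_background_tag: float = 0.02
    context_persistence: float = 0.6
    gps_jitter_m: float = 25.0
    feature_dim: int = 64
    feature_noise_sd: float = 0.5
    run_length: int = 15
    inter_run_gap_s: float = 30.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.5
    signal_center: tuple[int, int, int] | None = (10, 10, 10)
    signal_radius_mm: float = 7.5
    attenuation: float = 0.4
    noise_sd: float = 1.0
    prototype_sd: float = 0.7

    def __post_init__(self) -> None:
        for name in ("p_vivid", "p_remembered", "p_core_tag", "p_common_tag",
                     "p_background_tag", "context_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.extent_km > 30.0:
            raise ValueError("spatial extent must stay within 30 km")
        if self.signal_center is not None:
            c = np.asarray(self.signal_center)
            if np.any(c < 0) or np.any(c >= np.asarray(self.grid_shape)):
                raise ValueError("signal region center outside the grid")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score recovery against the generator."""

    signal_center: tuple[int, int, int] | None
    signal_radius_mm: float
    signal_voxels: np.ndarray  # (k, 3), empty when no signal
    attenuation: float
    noise_sd: float
    prototype_sd: float
    expected_signs: Mapping[str, int]  # in-region coefficient signs
    context_tag_indices: list[list[int]]
    common_tag_indices: list[int] = field(default_factory=list)
    context_ids: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0

    def signal_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if len(self.signal_voxels):
            m[tuple(self.signal_voxels.T)] = True
        return m

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signal_center": None
            if self.signal_center is None
            else list(self.signal_center),
            "signal_radius_mm": self.signal_radius_mm,
            "n_signal_voxels": int(len(self.signal_voxels)),
            "attenuation": self.attenuation,
            "noise_sd": self.noise_sd,
            "prototype_sd": self.prototype_sd,
            "expected_signs": dict(self.expected_signs),
            "context_tag_indices": self.context_tag_indices,
            "common_tag_indices": list(self.common_tag_indices),
            "context_ids": self.context_ids,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class Study:
    """A complete generated dataset for one synthetic experiment."""

    cfg: GeneratorConfig
    vocab: TagVocabulary
    events: dict[str, list[EventRecord]]
    features: dict[str, list[FeatureVector]]
    betas: dict[str, BetaVolume]
    ground_truth: GroundTruth


def _context_tag_sets(
    cfg: GeneratorConfig, vocab: TagVocabulary, rng
) -> tuple[list[list[int]], list[int]]:
    """Context core-tag groups plus cross-context routine tags.

    Core groups are disjoint (they make contexts discriminable); the routine
    tags are shared by all contexts with moderate probability, emulating
    everyday labels (being alone, using a computer, ...) that recur across
    unrelated episodes and give cross-context pairs a graded tag overlap.
    Both draws depend only on the study seed, so all participants share one
    tag geometry, as one recruitment pool would.
    """
    other_idx = vocab.index("other") if "other" in vocab else None
    candidates = [i for i in range(len(vocab)) if i != other_idx]
    need = cfg.n_contexts * cfg.tags_per_context + cfg.n_common_tags
    if need > len(candidates):
        raise ValueError("vocabulary too small for the requested tag groups")
    perm = rng.permutation(len(candidates))
    sets = []
    for c in range(cfg.n_contexts):
        lo = c * cfg.tags_per_context
        sets.append([candidates[k] for k in perm[lo : lo + cfg.tags_per_context]])
    lo = cfg.n_contexts * cfg.tags_per_context
    common = [candidates[k] for k in perm[lo : lo + cfg.n_common_tags]]
    return sets, common


def _simulate_participant_events(
    cfg: GeneratorConfig,
    vocab: TagVocabulary,
    pid: str,
    context_tags: list[list[int]],
    common_tags: list[int],
    rng: np.random.Generator,
) -> tuple[list[EventRecord], list[FeatureVector], list[int]]:
    n_tags = len(vocab)
    n_ctx = cfg.n_contexts
    # context anchor points: context 0 at home, others 0.5 km .. extent away
    home_lat = 40.0 + rng.uniform(-0.01, 0.01)
    home_lon = -83.0 + rng.uniform(-0.01, 0.01)
    ctx_lat = np.empty(n_ctx)
    ctx_lon = np.empty(n_ctx)
    ctx_lat[0], ctx_lon[0] = home_lat, home_lon
    for c in range(1, n_ctx):
        r_km = rng.uniform(0.5, max(0.6, cfg.extent_km / 2.0))
        theta = rng.uniform(0, 2 * np.pi)
        ctx_lat[c] = home_lat + r_km * np.cos(theta) * _DEG_PER_KM_LAT
        ctx_lon[c] = home_lon + r_km * np.sin(theta) * _DEG_PER_KM_LAT / np.cos(
            np.deg2rad(home_lat)
        )
    feat_proto = rng.normal(size=(n_ctx, cfg.feature_dim))

    per_day = max(1, int(np.ceil(cfg.n_events / cfg.duration_days)))
    contexts: list[int] = []
    lived: list[dict] = []
    for e in range(cfg.n_events):
        day, slot = divmod(e, per_day)
        if e == 0 or rng.uniform() > cfg.context_persistence:
            ctx = int(rng.integers(n_ctx))
        else:
            ctx = contexts[-1]
        contexts.append(ctx)
        hour = 9.0 + slot * (10.0 / per_day) + rng.uniform(-0.5, 0.5)
        clock = _EPOCH0 + day * 86_400.0 + hour * 3600.0
        jit = cfg.gps_jitter_m / 1000.0 * _DEG_PER_KM_LAT
        lat = ctx_lat[ctx] + rng.normal(0.0, jit)
        lon = ctx_lon[ctx] + rng.normal(0.0, jit)
        p = np.full(n_tags, cfg.p_background_tag)
        p[common_tags] = cfg.p_common_tag
        p[context_tags[ctx]] = cfg.p_core_tag
        tagvec = (rng.uniform(size=n_tags) < p).astype(np.uint8)
        if tagvec.sum() == 0:
            tagvec[vocab.index("other")] = 1
        remembered = bool(rng.uniform() < cfg.p_remembered)
        vivid = bool(rng.uniform() < cfg.p_vivid) if remembered else None
        lived.append(
            dict(clock=clock, lat=lat, lon=lon, tagvec=tagvec,
                 remembered=remembered, vivid=vivid, ctx=ctx)
        )

    # scanner presentation: random order, runs of `run_length` trials
    order = rng.permutation(cfg.n_events)
    onset = 0.0
    trial_dur = 8.0 + 0.5 + 2.5 + 0.5 + 2.5  # cue + ISIs + two questions
    events: list[EventRecord] = []
    features: list[FeatureVector] = []
    trial_contexts: list[int] = []
    for pos, ev_idx in enumerate(order):
        if pos > 0 and pos % cfg.run_length == 0:
            onset += cfg.inter_run_gap_s
        rec = lived[int(ev_idx)]
        events.append(
            EventRecord(
                event_id=f"{pid}_e{ev_idx:03d}",
                participant_id=pid,
                clock_time=rec["clock"],
                lat=float(np.clip(rec["lat"], -90, 90)),
                lon=float(np.clip(rec["lon"], -180, 180)),
                tagvec=rec["tagvec"],
                remembered=rec["remembered"],
                vivid=rec["vivid"],
                scanner_onset=onset,
                run_index=pos // cfg.run_length,
            )
        )
        f = feat_proto[rec["ctx"]] + rng.normal(
            0.0, cfg.feature_noise_sd, cfg.feature_dim
        )
        features.append(FeatureVector(f, "synthetic"))
        trial_contexts.append(rec["ctx"])
        onset += trial_dur + rng.uniform(4.0, 10.0)
    return events, features, trial_contexts


def simulate_events(
    cfg: GeneratorConfig, vocab: TagVocabulary | None = None
) -> tuple[dict[str, list[EventRecord]], dict[str, list[FeatureVector]], GroundTruth]:
    """Generate events and image features for every participant.

    Returns per-participant event lists (in scanner trial order), matching
    feature vectors, and a partially filled :class:`GroundTruth` (neural
    fields are completed by :func:`simulate_betas` /
    :func:`simulate_study`).
    """
    if vocab is None:
        vocab = load_vocabulary()
    root = np.random.SeedSequence(cfg.seed)
    ctx_ss, *part_ss = root.spawn(1 + cfg.n_participants)
    context_tags, common_tags = _context_tag_sets(
        cfg, vocab, np.random.default_rng(ctx_ss)
    )
    events: dict[str, list[EventRecord]] = {}
    features: dict[str, list[FeatureVector]] = {}
    context_ids: dict[str, list[int]] = {}
    for k in range(cfg.n_participants):
        pid = f"sub{k + 1:02d}"
        ev, fe, ctx = _simulate_participant_events(
            cfg, vocab, pid, context_tags, common_tags,
            np.random.default_rng(part_ss[k]),
        )
        events[pid] = ev
        features[pid] = fe
        context_ids[pid] = ctx
    gt = GroundTruth(
        signal_center=cfg.signal_center,
        signal_radius_mm=cfg.signal_radius_mm,
        signal_voxels=np.empty((0, 3), dtype=int),
        attenuation=cfg.attenuation,
        noise_sd=cfg.noise_sd,
        prototype_sd=cfg.prototype_sd,
        expected_signs={"Hamm": 1, "Hamm:Vivid": -1},
        context_tag_indices=context_tags,
        common_tag_indices=common_tags,
        context_ids=context_ids,
        seed=cfg.seed,
    )
    return events, features, gt


def _signal_voxels(cfg: GeneratorConfig) -> np.ndarray:
    if cfg.signal_center is None:
        return np.empty((0, 3), dtype=int)
    off = sphere_offsets(cfg.signal_radius_mm, cfg.voxel_size_mm)
    coords = np.asarray(cfg.signal_center) + off
    shape = np.asarray(cfg.grid_shape)
    ok = np.all((coords >= 0) & (coords < shape), axis=1)
    return coords[ok]


def simulate_betas(
    events: Sequence[EventRecord],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> BetaVolume:
    """Single-trial beta volume for one participant's trial sequence.

    Inside the signal region each trial's pattern is the sum of its tags'
    spatial prototypes, scaled by 1 (vivid) or the attenuation factor
    (non-vivid or unremembered), plus noise; elsewhere it is pure noise.
    """
    n_trials = len(events)
    data = rng.normal(
        0.0, cfg.noise_sd, size=(*cfg.grid_shape, n_trials)
    ).astype(np.float32)
    sig_vox = _signal_voxels(cfg)
    if len(sig_vox):
        n_tags = len(events[0].tagvec)
        prototypes = rng.normal(
            0.0, cfg.prototype_sd, size=(n_tags, len(sig_vox))
        )
        for t, ev in enumerate(events):
            gain = 1.0 if ev.vivid else cfg.attenuation
            pattern = gain * (ev.tagvec.astype(float) @ prototypes)
            data[sig_vox[:, 0], sig_vox[:, 1], sig_vox[:, 2], t] += pattern
    mask = np.ones(cfg.grid_shape, dtype=bool)
    return BetaVolume(data=data, voxel_size_mm=cfg.voxel_size_mm, mask=mask)


def simulate_study(
    cfg: GeneratorConfig, vocab: TagVocabulary | None = None
) -> Study:
    """Generate a full study: events, features, betas and ground truth."""
    if vocab is None:
        vocab = load_vocabulary()
    events, features, gt = simulate_events(cfg, vocab)
    gt.signal_voxels = _signal_voxels(cfg)
    beta_root = np.random.SeedSequence((cfg.seed, 1))
    betas: dict[str, BetaVolume] = {}
    for ss, pid in zip(beta_root.spawn(len(events)), events):
        betas[pid] = simulate_betas(events[pid], cfg, np.random.default_rng(ss))
    return Study(
        cfg=cfg, vocab=vocab, events=events, features=features,
        betas=betas, ground_truth=gt,
    )


def build_study_pairs(
    study: Study, config: PairFilterConfig = PairFilterConfig()
) -> dict[str, pd.DataFrame]:
    """Pair tables for every participant of a generated study."""
    return {
        pid: build_pairs(study.events[pid], study.features[pid], config)
        for pid in study.events
    }


def study_searchlights(
    study: Study,
    spec: ModelSpec,
    pairs: Mapping[str, pd.DataFrame] | None = None,
    **kwargs,
) -> list[SubjectSearchlight]:
    """One :class:`SubjectSearchlight` per participant, in participant order."""
    if pairs is None:
        pairs = build_study_pairs(study)
    return [
        SubjectSearchlight(study.betas[pid], pairs[pid], spec, **kwargs)
        for pid in study.events
    ]


def write_study(study: Study, out_dir: str | Path) -> None:
    """Serialize a study: events/features CSV, betas + mask NIfTI, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.vocab.to_json(out / "vocabulary.json")
    study.ground_truth.to_json(out / "ground_truth.json")
    for pid in study.events:
        events_to_csv(study.events[pid], study.vocab, out / f"{pid}_events.csv")
        features_to_csv(
            study.features[pid],
            out / f"{pid}_features.csv",
            ids=[e.event_id for e in study.events[pid]],
        )
        study.betas[pid].to_nifti(
            out / f"{pid}_betas.nii", out / f"{pid}_mask.nii"
        )
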