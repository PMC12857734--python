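"""End-to-end orchestration: read inputs, apply gates, compute statistics.

Each stage derives its own RNG seed deterministically from the single
config seed, records the config hash and seed in every output, and writes
machine-readable JSON plus human-readable CSV.  Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .groupstats import PermutationSpec, ks_two_sample, surrogate_permutation_test
from .morphometry import DendriteSegment, classify_spines, spine_density
from .photometry import binned_auc, correct_and_dff, peri_event_matrix, zscore_trace
from .spikes import BurstParams, burst_stats, classify_da_neuron
from .synth import (
    BurstyTrainSpec,
    PhotometrySimSpec,
    gen_bursty_spike_train,
    gen_photometry_trace,
    gen_spine_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "InsufficientDataError",
    "run_ephys_compare",
    "run_photometry_quant",
    "run_morpho_summarize",
    "run_simulate",
    "stage_seed",
]


class InsufficientDataError(RuntimeError):
    """Raised when too few units survive the inclusion gates."""


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable)."""

    seed: int = 0
    out_dir: str = "out"
    # ephys
    spikes_csv: str | None = None
    features_csv: str | None = None
    duration_s: float = 300.0
    onset_isi_max_ms: float = 80.0
    continuation_isi_max_ms: float = 160.0
    n_surrogates: int = 10_000
    # photometry: {"group_label": {"trace": path, "events": path}, ...}
    photometry_groups: dict = field(default_factory=dict)
    window_pre_s: float = 5.0
    window_post_s: float = 15.0
    bin_s: float = 5.0
    # morphometry
    spines_csv: str | None = None
    segments_csv: str | None = None
    # simulate
    simulate: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def burst_params(self) -> BurstParams:
        return BurstParams(self.onset_isi_max_ms, self.continuation_isi_max_ms)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _report_header(cfg: RunConfig, stage: str) -> dict:
    return {"config_hash": cfg.hash(), "seed": cfg.seed, "stage": stage}


def run_ephys_compare(cfg: RunConfig) -> dict:
    """Per-neuron burst statistics and two-group comparisons.

    Neurons failing the DA inclusion gate are excluded (and logged) before
    any group statistic.  For firing rate and %SWB separately, the group
    distributions are compared with the KS test and the group means with the
    surrogate permutation test.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains = dio.read_spikes_csv(cfg.spikes_csv, cfg.duration_s)
    feats = dio.read_features_csv(cfg.features_csv)
    params = cfg.burst_params()

    rows = []
    for _, frow in feats.iterrows():
        nid = str(frow["neuron_id"])
        included, reasons = classify_da_neuron(dio.features_from_row(frow))
        row = {
            "neuron_id": nid,
            "group": str(frow["group"]),
            "included": included,
            "reasons": ";".join(reasons),
            "firing_rate_hz": np.nan,
            "n_bursts": 0,
            "swb_percent": np.nan,
        }
        if not included:
            logger.info("neuron %s excluded: %s", nid, ",".join(reasons))
        if nid in trains:
            st = burst_stats(trains[nid], params)
            row.update(
                firing_rate_hz=st.firing_rate_hz,
                n_bursts=st.n_bursts,
                swb_percent=st.swb_percent,
            )
        rows.append(row)
    per_neuron = pd.DataFrame(rows)
    per_neuron.to_csv(out / "per_neuron.csv", index=False)

    groups = sorted(per_neuron["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two group labels required, got {groups}")
    inc = per_neuron[per_neuron["included"] & per_neuron["firing_rate_hz"].notna()]

    report = _report_header(cfg, "ephys_compare")
    report["groups"] = groups
    report["n_included"] = {g: int((inc["group"] == g).sum()) for g in groups}
    report["n_excluded"] = {
        g: int(((per_neuron["group"] == g) & ~per_neuron["included"]).sum())
        for g in groups
    }
    report["exclusions"] = per_neuron.loc[
        ~per_neuron["included"], ["neuron_id", "group", "reasons"]
    ].to_dict("records")

    for g in groups:
        if report["n_included"][g] < 2:
            raise InsufficientDataError(
                f"group {g!r}: fewer than 2 included neurons"
            )

    endpoints = {}
    for col in ("firing_rate_hz", "swb_percent"):
        a = inc.loc[inc["group"] == groups[0], col].to_numpy()
        b = inc.loc[inc["group"] == groups[1], col].to_numpy()
        ks = ks_two_sample(a, b)
        perm = surrogate_permutation_test(
            a,
            b,
            PermutationSpec(
                n_surrogates=cfg.n_surrogates,
                seed=stage_seed(cfg.seed, f"ephys:{col}"),
            ),
        )
        endpoints[col] = {
            "ks_d": ks.d_statistic,
            "ks_p": ks.p_value,
            "permutation": perm.to_dict(),
        }
    report["endpoints"] = endpoints
    dio.write_json_report(out / "ephys_report.json", report)
    return report


def run_photometry_quant(cfg: RunConfig) -> dict:
    """Peri-event binned z-score AUC per group, with per-bin comparisons."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(cfg.photometry_groups) != 2:
        raise ValueError("photometry_groups must name exactly two groups")

    window = (cfg.window_pre_s, cfg.window_post_s)
    auc_by_group: dict[str, np.ndarray] = {}
    report = _report_header(cfg, "photometry_quant")
    report["window_s"] = list(window)
    report["bin_s"] = cfg.bin_s
    report["groups"] = {}
    auc_rows = []
    mean_traces = {}

    for label in sorted(cfg.photometry_groups):
        paths = cfg.photometry_groups[label]
        trace = dio.read_trace(paths["trace"])
        events = dio.read_events_csv(paths["events"])["event_time_s"].to_numpy()
        dff = correct_and_dff(trace)
        # session-level z only as carrier; rows re-baselined on their pre span
        proc = zscore_trace(
            trace.time_s, dff, (trace.time_s[0], trace.time_s[-1]), trace.fs_hz
        )
        mat = peri_event_matrix(proc, events, window, rebaseline="pre")
        bins = [
            binned_auc(row, mat.fs_hz, cfg.bin_s, t_start_s=-cfg.window_pre_s)
            for row in mat.z
        ]
        auc = np.vstack([b.auc for b in bins])
        auc_by_group[label] = auc
        edges = bins[0].bin_edges_s
        for ev, arow in zip(mat.event_times_s, auc):
            for k, v in enumerate(arow):
                auc_rows.append(
                    {
                        "group": label,
                        "event_time_s": ev,
                        "bin_start_s": edges[k],
                        "bin_end_s": edges[k + 1],
                        "auc_z_s": v,
                    }
                )
        mean_traces[label] = mat.z.mean(axis=0)
        report["groups"][label] = {
            "n_events": int(mat.n_events),
            "n_dropped": int(mat.dropped_event_times_s.size),
            "dropped_event_times_s": mat.dropped_event_times_s.tolist(),
        }
        time_rel = mat.time_rel_s
    report["bin_edges_s"] = edges.tolist()

    pd.DataFrame(auc_rows).to_csv(out / "per_event_auc.csv", index=False)
    mt = pd.DataFrame({"time_rel_s": time_rel, **mean_traces})
    mt.to_csv(out / "mean_traces.csv", index=False)

    labels = sorted(auc_by_group)
    a_auc, b_auc = auc_by_group[labels[0]], auc_by_group[labels[1]]
    n_bins = min(a_auc.shape[1], b_auc.shape[1])
    per_bin = []
    for k in range(n_bins):
        perm = surrogate_permutation_test(
            a_auc[:, k],
            b_auc[:, k],
            PermutationSpec(
                n_surrogates=cfg.n_surrogates,
                seed=stage_seed(cfg.seed, f"photometry:bin{k}"),
            ),
        )
        per_bin.append(
            {"bin_start_s": float(edges[k]), **perm.to_dict()}
        )
    report["per_bin_comparison"] = per_bin
    dio.write_json_report(out / "photometry_report.json", report)
    return report


def run_morpho_summarize(cfg: RunConfig) -> dict:
    """Per-dendrite spine densities and per-group summary tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spines = classify_spines(pd.read_csv(cfg.spines_csv))
    segments = pd.read_csv(cfg.segments_csv)

    rows = []
    for _, seg in segments.iterrows():
        did = str(seg["dendrite_id"])
        sub = spines[spines["dendrite_id"].astype(str) == did]
        dens = spine_density(DendriteSegment(did, float(seg["length_um"]), sub))
        row = {"dendrite_id": did, "length_um": float(seg["length_um"]), **{
            f"density_{k}_per10um": v for k, v in dens.items()
        }}
        if "group" in segments.columns:
            row["group"] = str(seg["group"])
        rows.append(row)
    per_dendrite = pd.DataFrame(rows)
    per_dendrite.to_csv(out / "per_dendrite.csv", index=False)

    report = _report_header(cfg, "morpho_summarize")
    report["n_dendrites"] = len(per_dendrite)
    report["n_spines"] = len(spines)
    if "group" in per_dendrite.columns:
        summary = (
            per_dendrite.groupby("group")[
                [c for c in per_dendrite.columns if c.startswith("density_")]
            ]
            .mean()
            .round(6)
        )
        report["group_means"] = summary.to_dict("index")
        summary.to_csv(out / "group_summary.csv")
    dio.write_json_report(out / "morpho_report.json", report)
    return report


def run_simulate(cfg: RunConfig) -> dict:
    """Generate synthetic inputs (with ground-truth sidecars) for all stages.

    ``cfg.simulate`` keys: ``ephys`` (n1, n2, p_burst_1, p_burst_2,
    duration_s, ...), ``photometry`` (PhotometrySimSpec fields per group),
    ``spines`` (n, p_mushroom).  Any subset may be present.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulate
    truth: dict = _report_header(cfg, "simulate")

    if "ephys" in sim:
        e = sim["ephys"]
        trains, feat_rows, swb_truth = {}, [], {}
        for gi, (glabel, n_key, p_key) in enumerate(
            [("group1", "n1", "p_burst_1"), ("group2", "n2", "p_burst_2")]
        ):
            for j in range(int(e[n_key])):
                nid = f"{glabel}_n{j:03d}"
                spec = BurstyTrainSpec(
                    rate_events_hz=e.get("rate_events_hz", 2.0),
                    p_burst=e[p_key],
                    spikes_per_burst=e.get("spikes_per_burst", 3),
                    duration_s=e.get("duration_s", 300.0),
                    seed=stage_seed(cfg.seed, f"ephys:{nid}"),
                )
                train, tr = gen_bursty_spike_train(spec, nid)
                trains[nid] = train
                swb_truth[nid] = (
                    100.0 * tr["in_burst"].sum() / len(tr) if len(tr) else 0.0
                )
                feat_rows.append(
                    {
                        "neuron_id": nid,
                        "group": glabel,
                        "triphasic": True,
                        "duration_ms": 2.5,
                        "start_to_trough_ms": 1.3,
                        "mean_rate_hz": min(9.5, max(1.5, train.n_spikes / spec.duration_s)),
                    }
                )
        dio.write_spikes_csv(out / "spikes.csv", trains)
        pd.DataFrame(feat_rows).to_csv(out / "features.csv", index=False)
        truth["ephys_true_swb_percent"] = swb_truth

    if "photometry" in sim:
        for label, kw in sorted(sim["photometry"].items()):
            spec = PhotometrySimSpec(
                **{**kw, "seed": stage_seed(cfg.seed, f"photometry:{label}")}
            )
            trace, events = gen_photometry_trace(spec)
            dio.write_trace_csv(out / f"trace_{label}.csv", trace)
            pd.DataFrame(
                {"event_time_s": events, "label": label}
            ).to_csv(out / f"events_{label}.csv", index=False)
            truth.setdefault("photometry_events", {})[label] = events.tolist()

    if "spines" in sim:
        s = sim["spines"]
        table = gen_spine_table(
            int(s["n"]), float(s["p_mushroom"]), seed=stage_seed(cfg.seed, "spines")
        )
        table.to_csv(out / "spines.csv", index=False)
        truth["spines_p_mushroom"] = float(s["p_mushroom"])

    dio.write_json_report(out / "ground_truth.json", truth)
    return truth
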