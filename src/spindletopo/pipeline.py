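"""End-to-end orchestration: cohort -> topographies -> statistics report.

The pipeline runs the stages in their scientific order: wake encoding
pattern (epoch spectra, percentile rejection, contrast, group cluster test,
collapse), sleep event detection (spindles, SOs), SO-phase coupling,
per-participant encoding-sleep overlap, and the group statistics including
the two topography-shuffling permutation nulls against behavior.  A run is
fully determined by its configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .behavior import fisher_z, retention as retention_score
from .encoding import (ContrastMap, EncodingTopography, cluster_permutation,
                       collapse_topography, contrast, epoch_psd,
                       percentile_reject)
from .events import (DetectionParams, characterize, detect_slow_oscillations,
                     detect_spindles, spindle_so_phase, split_by_coupling)
from .io_core import ArtifactMask, Hypnogram, Montage, Recording
from .stats import (CHARACTERISTICS, behavior_correlation, coupling_contrast,
                    overlap, partial_spearman, permutation_null,
                    posthoc_tests, rm_anova_2x3)
from .synthetic import ParticipantBundle, SynthConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                    # "simulate" or "ingest"
    synth: SynthConfig | None = None          # simulate mode
    participants: list[dict] = field(default_factory=list)  # ingest mode
    behavior_path: str | None = None          # ingest mode
    montage_path: str | None = None           # ingest mode
    detection: DetectionParams = field(default_factory=DetectionParams)
    n_perm: int = 1000
    cell_alpha: float = 0.05
    cluster_alpha: float = 0.05
    reject_pct: float = 95.0
    fallback_band: tuple[float, float] = (6.0, 20.0)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "simulate" and self.synth is None:
            self.synth = SynthConfig(seed=self.seed)


@dataclass
class PipelineReport:
    """Everything one run computes, plus what was written where."""

    encoding_topos: pd.DataFrame       # participants x channels
    sleep_topos: dict                  # (pid, kind) -> EventTopography
    events: pd.DataFrame               # pooled event table
    overlaps: pd.DataFrame             # one row per participant x 6 measures
    cluster: object                    # group ClusterResult
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    partials: pd.DataFrame
    behavior: pd.DataFrame
    behavior_corr: tuple[float, float]
    perm_encoding: object
    perm_spindle: object
    coupling: dict
    manifest: dict


def _participant_contrast(enc: Recording, pvt: Recording, pid: str,
                          reject_pct: float) -> ContrastMap:
    s_enc = epoch_psd(enc, "encoding")
    s_pvt = epoch_psd(pvt, "pvt")
    masks = (percentile_reject(s_enc, reject_pct),
             percentile_reject(s_pvt, reject_pct))
    return contrast(s_enc, s_pvt, masks, participant_id=pid)


def _detect_participant(bundle: ParticipantBundle, params: DetectionParams
                        ) -> tuple[pd.DataFrame, dict]:
    """Events (with phases) and the per-kind topographies for one nap."""
    rec, hyp, art = bundle.sleep, bundle.hypnogram, bundle.artifacts
    spindles = detect_spindles(rec, hyp, art, params)
    sos = detect_slow_oscillations(rec, hyp, art, params)
    spindles = spindle_so_phase(rec, spindles, params)
    labels = rec.channel_labels
    topos = {
        "spindle": characterize(spindles, hyp, art, rec.fs, rec.n_samples,
                                labels),
        "so": characterize(sos, hyp, art, rec.fs, rec.n_samples, labels),
    }
    higher, lower = split_by_coupling(spindles)
    topos["spindle_higher"] = characterize(higher, hyp, art, rec.fs,
                                           rec.n_samples, labels)
    topos["spindle_lower"] = characterize(lower, hyp, art, rec.fs,
                                          rec.n_samples, labels)
    events = pd.concat([spindles, sos], ignore_index=True)
    events.insert(0, "participant", bundle.participant_id)
    return events, topos


def analyze_cohort(bundles: list[ParticipantBundle], montage: Montage,
                   config: RunConfig) -> PipelineReport:
    """Run every analysis stage on an in-memory cohort."""
    rng = np.random.default_rng(config.seed)
    n = len(bundles)
    if n < 2:
        raise ValueError("need at least 2 participants")

    # --- stage 1: wake encoding patterns -------------------------------
    contrasts = []
    for b in bundles:
        try:
            contrasts.append(_participant_contrast(
                b.encoding, b.pvt, b.participant_id, config.reject_pct))
        except Exception as exc:  # noqa: BLE001 - abort with context
            raise RuntimeError(
                f"encoding stage failed for {b.participant_id}: {exc}"
            ) from exc
    cluster = cluster_permutation(contrasts, montage, config.n_perm,
                                  config.cell_alpha, config.cluster_alpha,
                                  rng=rng)
    enc_topos = [collapse_topography(c, cluster.sig_bins,
                                     config.fallback_band)
                 for c in contrasts]
    enc_df = pd.DataFrame([t.values for t in enc_topos],
                          index=[t.participant_id for t in enc_topos],
                          columns=montage.channel_labels)

    # --- stage 2: sleep events + coupling ------------------------------
    all_events = []
    sleep_topos: dict = {}
    for b in bundles:
        try:
            ev, topos = _detect_participant(b, config.detection)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"detection stage failed for {b.participant_id}: {exc}"
            ) from exc
        all_events.append(ev)
        for kind, topo in topos.items():
            sleep_topos[(b.participant_id, kind)] = topo
    events = pd.concat(all_events, ignore_index=True)

    # --- stage 3: per-participant overlap ------------------------------
    rows = []
    for t in enc_topos:
        for kind in ("spindle", "so"):
            topo = sleep_topos[(t.participant_id, kind)]
            for ch in CHARACTERISTICS:
                r = overlap(t, topo, ch)
                rows.append({"participant": t.participant_id,
                             "kind": kind, "characteristic": ch,
                             "rho": r.rho, "z": r.z,
                             "n_channels": r.n_channels})
    overlaps = pd.DataFrame(rows)
    z_wide = overlaps.pivot_table(index="participant", columns=["kind",
                                  "characteristic"], values="z")
    z_table = np.stack([
        np.column_stack([z_wide[("spindle", c)] for c in CHARACTERISTICS]),
        np.column_stack([z_wide[("so", c)] for c in CHARACTERISTICS]),
    ], axis=1)

    # --- stage 4: group statistics -------------------------------------
    anova = rm_anova_2x3(z_table)
    posthoc = posthoc_tests(z_table)

    prows = []
    for target, control in [("amplitude", "duration"),
                            ("amplitude", "density"),
                            ("duration", "amplitude"),
                            ("density", "amplitude")]:
        zs = []
        for t in enc_topos:
            topo = sleep_topos[(t.participant_id, "spindle")]
            pr = partial_spearman(t.values,
                                  topo.vector(target).to_numpy(),
                                  topo.vector(control).to_numpy())
            zs.append(fisher_z(pr))
        zs = np.asarray(zs, dtype=float)
        ok = np.isfinite(zs)
        tt, pp = (sps.ttest_1samp(zs[ok], 0.0) if ok.sum() > 1
                  else (np.nan, np.nan))
        prows.append({"target": target, "control": control,
                      "mean_z": float(np.nanmean(zs)), "t": float(tt),
                      "df": int(ok.sum()) - 1, "p": float(pp)})
    partials = pd.DataFrame(prows)

    behavior = pd.DataFrame([b.behavior for b in bundles]).set_index(
        "participant_id")
    if "retention_pct" not in behavior.columns:
        behavior["retention_pct"] = [
            retention_score(r.pre_z, r.post_z)
            for r in behavior.itertuples()
        ]
    ret = behavior.loc[enc_df.index, "retention_pct"].to_numpy(float)

    amp_z = z_wide[("spindle", "amplitude")].loc[enc_df.index].to_numpy()
    behavior_corr = behavior_correlation(amp_z, ret)

    spin_amp = np.vstack([
        sleep_topos[(pid, "spindle")].vector("amplitude").to_numpy()
        for pid in enc_df.index
    ])
    perm_enc = permutation_null(enc_df.to_numpy(), spin_amp, ret,
                                "encoding", config.n_perm, rng)
    perm_spin = permutation_null(enc_df.to_numpy(), spin_amp, ret,
                                 "spindle", config.n_perm, rng)

    z_hi, z_lo = [], []
    for t in enc_topos:
        for which, dest in (("spindle_higher", z_hi),
                            ("spindle_lower", z_lo)):
            topo = sleep_topos[(t.participant_id, which)]
            dest.append(overlap(t, topo, "amplitude").z
                        if topo.table["n_events"].sum() > 0 else np.nan)
    coupling = coupling_contrast(z_hi, z_lo)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_participants": n,
        "n_perm": config.n_perm,
        "significant_bins_hz": (cluster.freqs[cluster.sig_bins].tolist()
                                if cluster.sig_bins.size else []),
        "config_hash": hashlib.sha256(
            repr(sorted(asdict(config.detection).items())).encode()
        ).hexdigest()[:16],
    }
    return PipelineReport(
        encoding_topos=enc_df, sleep_topos=sleep_topos, events=events,
        overlaps=overlaps, cluster=cluster, anova=anova, posthoc=posthoc,
        partials=partials, behavior=behavior, behavior_corr=behavior_corr,
        perm_encoding=perm_enc, perm_spindle=perm_spin, coupling=coupling,
        manifest=manifest,
    )


def _load_ingest_cohort(config: RunConfig
                        ) -> tuple[list[ParticipantBundle], Montage]:
    from .io_core import (read_artifacts, read_hypnogram, read_montage,
                          read_recording)

    if config.montage_path is None:
        raise ValueError("ingest mode requires montage_path")
    montage = read_montage(config.montage_path)
    behavior = (pd.read_csv(config.behavior_path, sep="\t")
                if config.behavior_path else pd.DataFrame())
    bundles = []
    for spec in config.participants:
        pid = spec["id"]
        row = {}
        if len(behavior):
            match = behavior[behavior["participant_id"] == pid]
            if len(match):
                row = match.iloc[0].to_dict()
        row.setdefault("participant_id", pid)
        bundles.append(ParticipantBundle(
            participant_id=pid,
            encoding=read_recording(spec["encoding"]),
            pvt=read_recording(spec["pvt"]),
            sleep=read_recording(spec["sleep"]),
            hypnogram=read_hypnogram(spec["hypnogram"]),
            artifacts=(read_artifacts(spec["artifacts"])
                       if spec.get("artifacts") else ArtifactMask([])),
            behavior=row,
        ))
    return bundles, montage


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Write the report bundle as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.encoding_topos.rename_axis("participant").to_csv(
        out / "encoding_topographies.tsv", sep="\t")
    report.events.to_csv(out / "events.tsv", sep="\t", index=False)
    report.overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
    topo_rows = []
    for (pid, kind), topo in report.sleep_topos.items():
        t = topo.table.reset_index()
        t.insert(0, "participant", pid)
        t.insert(1, "kind", kind)
        topo_rows.append(t)
    pd.concat(topo_rows, ignore_index=True).to_csv(
        out / "sleep_topographies.tsv", sep="\t", index=False)
    report.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    report.posthoc.to_csv(out / "posthoc.tsv", sep="\t", index=False)
    report.partials.to_csv(out / "partial_correlations.tsv", sep="\t",
                           index=False)
    report.behavior.to_csv(out / "behavior.tsv", sep="\t")
    perm = {
        "behavior_correlation": {"rho": report.behavior_corr[0],
                                 "p": report.behavior_corr[1]},
        "coupling_contrast": report.coupling,
        "clusters": [
            {"stat": c["stat"], "p": c["p"], "sign": c["sign"],
             "n_cells": int(len(c["cells"]))}
            for c in report.cluster.clusters
        ],
    }
    for name, pn in (("shuffle_encoding", report.perm_encoding),
                     ("shuffle_spindle", report.perm_spindle)):
        perm[name] = {"observed_r": pn.observed_r, "p": pn.p,
                      "p_two_sided": pn.p_two_sided, "n_perm": pn.n_perm}
    with open(out / "statistics.json", "w") as fh:
        json.dump(perm, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Simulate or ingest a cohort, run every stage, optionally write it."""
    if config.mode == "simulate":
        cohort = generate_cohort(config.synth)
        bundles = [b for b, _ in cohort]
        montage = config.synth.montage
    else:
        bundles, montage = _load_ingest_cohort(config)
    report = analyze_cohort(bundles, montage, config)
    if config.out_dir:
        write_report(report, config.out_dir)
        logger.info("report written to %s", config.out_dir)
    return report
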