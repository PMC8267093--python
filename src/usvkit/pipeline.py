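"""End-to-end pipeline: simulate -> (detect) -> featurize -> variable
clustering -> call typing -> transitions -> group statistics.

Stages communicate via on-disk schema files inside the report directory, so
any stage can be re-run standalone.  Everything is a pure function of
(cohort config, pipeline config, master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, synthetic
from .calltypes import fit_call_types, occurrence_table, remove_noise_cluster
from .config import PipelineConfig
from .features import attach_voc_number, features_frame
from .groupstats import kruskal_wallis, manova_roy, steel_dwass, tukey_kramer
from .io_formats import FEATURE_COLUMNS, CallRecord, call_table_frame, write_call_table
from .transitions import (build_sequences, edge_list, edges_frame, group_average,
                          to_dot, transition_counts)
from .varclus import VarClus

log = logging.getLogger("usvkit")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cohort: synthetic.CohortConfig, config: PipelineConfig,
            outdir: str | Path, overwrite: bool = False) -> Path:
    """Run the full pipeline; returns the report directory.

    With ``cohort.audio`` false the feature stage runs on the generator's
    truth contours; with it true, sessions are rendered to audio and passed
    through the spectral detector first.
    """
    t_start = time.time()
    config.validate()
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is non-empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    (out / "transitions").mkdir(exist_ok=True)

    # -- stage 1: simulate --------------------------------------------------
    log.info("simulate: cohort of %d groups, master seed %d",
             len(cohort.groups), cohort.master_seed)
    sessions, manifest = synthetic.simulate_cohort(cohort)
    log.info("simulate: %d sessions, %d calls", len(sessions),
             int(manifest["n_calls"].sum()))

    # -- stage 2: calls + contours (truth path or audio/detection path) -----
    records: list[CallRecord] = []
    contours = []
    rng = np.random.default_rng(np.random.SeedSequence(cohort.master_seed).spawn(1)[0])
    for sess_contours, truth in sessions:
        if cohort.audio:
            rec = synthetic.render_audio(sess_contours, cohort.sample_rate,
                                         cohort.snr_db, rng)
            rec.animal_id, rec.group = truth.animal_id, truth.group
            recs, conts = detection.detect(rec, config)
            records += recs
            contours += conts
        else:
            for _, row in truth.calls.iterrows():
                records.append(CallRecord(
                    call_id=row["call_id"], animal_id=row["animal_id"],
                    group=row["group"], onset_s=row["onset_s"],
                    offset_s=row["offset_s"], is_truth=True))
            contours += sess_contours
    log.info("calls: %d (%s path)", len(records),
             "detection" if cohort.audio else "truth-contour")

    # -- stage 3: features ---------------------------------------------------
    feats = features_frame(contours, config.features)
    meta = pd.DataFrame({
        "call_id": [r.call_id for r in records],
        "animal_id": [r.animal_id for r in records],
        "group": [r.group for r in records],
        "onset_s": [r.onset_s for r in records],
        "offset_s": [r.offset_s for r in records]})
    table = pd.concat([meta.reset_index(drop=True), feats.reset_index(drop=True)],
                      axis=1)
    for rec, (_, row) in zip(records, feats.iterrows()):
        rec.features = row.to_dict()
    write_call_table(records, out / "calls.csv")
    log.info("features: wrote calls.csv with %d rows", len(table))

    # -- stage 4: group parameter report (Table-1 style) ---------------------
    _feature_report(table, config).to_csv(out / "table1.csv", index=False)
    log.info("stats: wrote table1.csv")

    # -- stage 5: variable clustering ----------------------------------------
    with_voc = attach_voc_number(table[list(FEATURE_COLUMNS)], table["animal_id"])
    vc = VarClus(with_voc).fit()
    (out / "clusters.json").write_text(json.dumps(vc.to_dict(), indent=2) + "\n")
    scores = vc.transform(with_voc)
    scores.insert(0, "animal_id", table["animal_id"].to_numpy())
    scores.insert(1, "group", table["group"].to_numpy())
    scores.to_csv(out / "cluster_scores.csv", index=False, float_format="%.10g")
    log.info("varclus: %d clusters %s", vc.n_clusters,
             [len(c) for c in vc.clusters])

    # -- stage 6: call typing ------------------------------------------------
    model, raw = fit_call_types(table[list(FEATURE_COLUMNS)],
                                k=config.typing.k_initial,
                                restarts=config.typing.restarts,
                                seed=config.typing.seed)
    model, types = remove_noise_cluster(
        model, raw, table[list(FEATURE_COLUMNS)],
        rule=config.typing.noise_rule, noise_cluster=config.typing.noise_cluster)
    for rec, t in zip(records, types):
        rec.call_type = int(t) if t > 0 else None
    table["call_type"] = types
    typed = [r for r in records if r.call_type is not None]
    write_call_table(typed, out / "typed.csv")
    occ = occurrence_table(types, table["animal_id"], table["group"])
    occ.to_csv(out / "occurrence.csv", float_format="%.10g")
    type_cols = [c for c in occ.columns if c.startswith("type_")]
    manova = manova_roy(occ[type_cols].to_numpy(), occ["group"].to_numpy())
    posthoc = {}
    for col in type_cols:
        rep = tukey_kramer(occ[col].to_numpy(), occ["group"].to_numpy(),
                           alpha=config.stats.alpha)
        posthoc[col] = {
            "pairs": [{"a": p.group_a, "b": p.group_b, "q": p.statistic,
                       "p": p.p_value, "significant": bool(p.significant)}
                      for p in rep.pairs],
            "letters": rep.letters}
    (out / "manova.json").write_text(json.dumps(
        {"manova_roy": {k: v for k, v in manova.items()},
         "tukey_kramer": posthoc}, indent=2, default=float) + "\n")
    log.info("typing: noise cluster %s removed, %d typed calls",
             model.noise_cluster, len(typed))

    # -- stage 7: transitions --------------------------------------------------
    seqs = build_sequences(typed, gap_s=config.transitions.gap_s)
    group_of = {r.animal_id: r.group for r in typed}
    per_group: dict[str, list] = {}
    for animal, seq in sorted(seqs.items()):
        tm = transition_counts(seq)
        pd.DataFrame(tm.counts).to_csv(
            out / "transitions" / f"{animal}_counts.csv", index=False)
        per_group.setdefault(group_of[animal], []).append(tm)
    edge_rows = []
    for group, mats in sorted(per_group.items()):
        avg = group_average(mats)
        pd.DataFrame(avg).to_csv(out / "transitions" / f"{group}_joint.csv",
                                 index=False, float_format="%.10g")
        edges = edge_list(avg, config.transitions.edge_threshold)
        df = edges_frame(edges)
        df.insert(0, "group", group)
        edge_rows.append(df)
        (out / "transitions" / f"{group}.dot").write_text(to_dot(edges, group))
    pd.concat(edge_rows, ignore_index=True).to_csv(
        out / "transitions" / "edges.csv", index=False, float_format="%.10g")
    log.info("transitions: %d groups", len(per_group))

    # -- manifest ---------------------------------------------------------------
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest_obj = {
        "master_seed": cohort.master_seed,
        "config": config.to_dict(),
        "cohort": {**dataclasses.asdict(cohort),
                   "groups": {g: list(v) for g, v in cohort.groups.items()}},
        "elapsed_s": round(time.time() - t_start, 2),
        "files": {str(p.relative_to(out)): _digest(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest_obj, indent=2) + "\n")
    log.info("done in %.1f s", time.time() - t_start)
    return out


def _feature_report(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per-feature group means +/- SEM with Kruskal-Wallis and letter display."""
    unit = config.stats.unit
    groups_order = list(dict.fromkeys(table["group"]))
    rows = []
    for feat in FEATURE_COLUMNS:
        if unit == "animal":
            agg = table.groupby(["animal_id", "group"], as_index=False)[feat].mean()
            vals, labs = agg[feat].to_numpy(), agg["group"].to_numpy()
        else:
            vals, labs = table[feat].to_numpy(), table["group"].to_numpy()
        H, df, p = kruskal_wallis(vals, labs)
        rep = steel_dwass(vals, labs, alpha=config.stats.alpha)
        row = {"feature": feat, "kw_H": H, "kw_df": df, "kw_p": p}
        for g in groups_order:
            sub = vals[labs == g]
            row[f"{g}_mean"] = sub.mean()
            row[f"{g}_sem"] = sub.std(ddof=1) / np.sqrt(sub.size)
            row[f"{g}_letters"] = rep.letters.get(g, "")
        rows.append(row)
    return pd.DataFrame(rows)
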