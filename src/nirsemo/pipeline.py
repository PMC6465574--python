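"""End-to-end pipeline: simulate -> preprocess -> behavior -> decode -> topo.

Binds the stages together, mirrors the published result tables as CSV
output, and writes a run manifest (config hash, seeds, versions) so that
a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, neurocorrelation, preprocessing, synthetic
from .io import RunConfig, write_events_csv, write_ratings_csv
from .optics import DEFAULT_EXTINCTION, ExtinctionTable, RawRecording, compute_delta_od, invert_mbll

logger = logging.getLogger(__name__)

__all__ = ["derive_seed", "preprocess_recording", "run_pipeline"]

CONTRASTS = [
    ("encouragement", "negative"),
    ("playfulness", "negative"),
    ("harmony", "negative"),
    ("encouragement", "playfulness"),
    ("playfulness", "harmony"),
    ("encouragement", "harmony"),
]


def derive_seed(*parts: int) -> int:
    """A reproducible child seed (< 2^31) from integer components."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def preprocess_recording(
    raw: RawRecording, config: RunConfig, ext: ExtinctionTable | None = None,
    participant_id: object = None,
) -> list[preprocessing.FeatureSample]:
    """Raw intensity -> band-pass -> MBLL -> baseline -> spatial features."""
    if ext is None:
        ext = (
            ExtinctionTable.from_config(config.extinction_config)
            if config.extinction_config
            else DEFAULT_EXTINCTION
        )
    events = preprocessing.validate_events(
        raw.events, min_duration_s=config.min_duration_s,
        min_lead_s=config.baseline_window_s,
    )
    filtered = preprocessing.bandpass_intensity(
        raw, config.filter_low_hz, config.filter_high_hz
    )
    od = compute_delta_od(filtered)
    hemo = invert_mbll(od, ext, raw.montage)
    hemo = preprocessing.baseline_correct(hemo, events, config.baseline_window_s)
    windows = preprocessing.extract_samples(
        hemo, events, config.sample_window_s, config.n_sample_windows
    )
    return preprocessing.build_features(
        windows, participant_id, n_channels=raw.montage.n_channels
    )


def _decode_participant(
    features, selected: dict, scores: pd.DataFrame, config: RunConfig, pseed: int
) -> list[decoding.DecodeResult]:
    results = []
    for ci, (a, b) in enumerate(CONTRASTS):
        if b == "negative":
            clips_a, clips_b = selected[a], selected[b]
        else:
            # cluster-vs-cluster: the two top-6 sets must not share clips
            clips_a, clips_b = behavior.select_top_clips_disjoint(
                scores, a, b, config.top_k_clips
            )
        for chrom in preprocessing.CHROMOPHORES:
            results.append(
                decoding.decode_contrast(
                    features,
                    clips_a,
                    clips_b,
                    chromophore=chrom,
                    contrast=(a, b),
                    seed=derive_seed(pseed, ci),
                    n_shuffles=config.n_shuffles,
                    c=config.svm_c,
                    with_permutation=config.with_permutation,
                )
            )
    return results


def run_pipeline(config: RunConfig, design: synthetic.SimDesign | None = None) -> dict:
    """Run the full synthetic-cohort analysis and write result tables.

    Stages: simulate ratings and recordings; preprocess each recording to
    spatial features; rating analytics (ICC, manipulation checks,
    correlations, MDS, cluster scores, top-clip selection); per-participant
    SVM decoding of the six contrasts for both chromophores with
    permutation chance levels; correlation topographies.  Returns a result
    bundle dict and writes CSVs plus a manifest under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = synthetic.SimDesign(
            n_participants=config.n_participants,
            fs=config.fs,
            duration_range_s=(config.min_duration_s, config.max_duration_s),
        )
    seed = config.seed
    bundle: dict = {"config": config, "design": design}

    # --- simulate: ratings -------------------------------------------------
    logger.info("stage simulate: %d participants, %d clips", design.n_participants,
                design.n_clips)
    ratings, rating_truth = synthetic.gen_ratings(design, seed)
    write_ratings_csv(ratings, out / "ratings.csv")
    bundle["ratings"] = ratings

    # --- behavior ----------------------------------------------------------
    logger.info("stage behavior")
    icc = pd.Series(
        {item: behavior.icc_per_item(ratings, item) for item in ratings.items},
        name="icc",
    )
    icc.rename_axis("item").to_csv(out / "icc.csv")
    checks = {
        emo: behavior.manipulation_check(ratings, emo) for emo in behavior.POSITIVE_ITEMS
    }
    pd.concat(
        [c.posthoc.assign(target=emo) for emo, c in checks.items()], ignore_index=True
    ).to_csv(out / "manipulation_checks.csv", index=False)
    r, p, stars = behavior.rating_correlations(ratings)
    r.round(2).to_csv(out / "rating_correlations.csv")
    pos_block = r.loc[list(behavior.POSITIVE_ITEMS), list(behavior.POSITIVE_ITEMS)]
    mds = behavior.mds_embed(1.0 - pos_block, seed=derive_seed(seed, 101))
    mds.coords.assign(stress1=mds.stress1).to_csv(out / "mds_solution.csv")
    clip_means = ratings.clip_means("positive")
    scores = behavior.cluster_scores(clip_means, design.clusters)
    scores.to_csv(out / "cluster_scores.csv")
    selected = {
        name: behavior.select_top_clips(scores[name], config.top_k_clips)
        for name in design.clusters.names
    }
    selected["negative"] = ratings.clips.loc[
        ratings.clips["condition"] == "negative", "clip_id"
    ].tolist()
    pd.Series(selected, name="clips").to_json(out / "selected_clips.json")
    bundle.update(icc=icc, checks=checks, correlations=r, mds=mds,
                  cluster_scores=scores, selected=selected)

    # --- preprocess + decode + topo, one participant at a time -------------
    logger.info("stage preprocess/decode: %d contrasts x 2 chromophores",
                len(CONTRASTS))
    all_results: list[decoding.DecodeResult] = []
    topo_maps: dict = {}
    valence = ratings.clip_means("positive")["valence"]
    score_table = scores.join(valence)
    for pidx, (pid, raw, truth) in enumerate(synthetic.gen_cohort(design, seed)):
        features = preprocess_recording(raw, config, participant_id=pid)
        all_results.extend(
            _decode_participant(
                features, selected, scores, config, derive_seed(seed, 7, pidx)
            )
        )
        for chrom in preprocessing.CHROMOPHORES:
            responses = neurocorrelation.clip_responses(features, chrom)
            responses = responses.loc[[c for c in clip_means.index]]
            for score_name in score_table.columns:
                tm = neurocorrelation.channel_score_correlation(
                    responses, score_table[score_name], chrom, score_name,
                    channel_id=raw.montage.channel_id,
                )
                topo_maps.setdefault((chrom, score_name), []).append(tm)
        logger.info("participant %s done", pid)

    # --- summaries ---------------------------------------------------------
    tables = {}
    for chrom in preprocessing.CHROMOPHORES:
        vs_neg = [
            r for r in all_results
            if r.chromophore == chrom and r.contrast[1] == "negative"
        ]
        within = [
            r for r in all_results
            if r.chromophore == chrom and r.contrast[1] != "negative"
        ]
        tables[f"{chrom}_vs_negative"] = decoding.summarize_group(vs_neg)
        tables[f"{chrom}_within_clusters"] = decoding.summarize_group(within)
    for name, table in tables.items():
        table.to_csv(out / f"accuracies_{name}.csv")
    if config.with_permutation:
        chance_rows = [
            {
                "participant": r.participant_id,
                "chromophore": r.chromophore,
                "contrast": " vs ".join(r.contrast),
                "chance_mean": r.chance_mean,
                "chance_sd": r.chance_sd,
            }
            for r in all_results
        ]
        pd.DataFrame(chance_rows).to_csv(out / "chance_levels.csv", index=False)

    group_maps = {
        key: neurocorrelation.group_topography(maps) for key, maps in topo_maps.items()
    }
    pd.concat(
        [neurocorrelation.topomap_to_frame(tm) for tm in group_maps.values()],
        ignore_index=True,
    ).to_csv(out / "topographies.csv", index=False)

    bundle.update(results=all_results, tables=tables, topographies=group_maps)

    # --- manifest ----------------------------------------------------------
    import nirsemo

    manifest = {
        "config_hash": config.digest(),
        "seed": seed,
        "n_participants": design.n_participants,
        "n_results": len(all_results),
        "versions": {
            "nirsemo": getattr(nirsemo, "__version__", "0"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d decode results", len(all_results))
    return bundle
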