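"""End-to-end orchestration of the screen and traction-force arms.

``run_screen`` chains synthetic data (or pre-computed adhesion tables)
through morphometrics and KS-based hit calling; ``run_tfm`` chains
pillar-movie simulation through the full traction-force pipeline and
the cross-condition half-time comparison.  Both write a run manifest
(config echo + seeds + record counts) so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fadynamics import screen_stats, synthetic, tfm
from fadynamics.io import write_manifest

__all__ = ["run_screen", "run_tfm", "hit_table"]


def hit_table(calls: Sequence[screen_stats.HitCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene": c.gene, "category": c.category, "deselected": c.deselected}
        for name, ks in (
            ("dmso_vs_control", c.ks_dmso_vs_control),
            ("noco_vs_dmso", c.ks_noco_vs_dmso),
            ("washout_vs_noco", c.ks_washout_vs_noco),
        ):
            row[f"{name}_signed_d"] = ks.signed_d
            row[f"{name}_log10_p"] = ks.log10_p
            row[f"{name}_score"] = ks.score
        rows.append(row)
    return pd.DataFrame(rows)


def run_screen(
    layout: pd.DataFrame,
    effects: Mapping[str, Sequence[float]],
    seed: int = 0,
    thresholds: screen_stats.HitThresholds | None = None,
    deselect: Sequence[str] = (),
    use_rendered_images: bool = False,
    adhesions_per_image: int = 200,
    images_per_well: int = 4,
    base_config: synthetic.FaImageConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate and score a three-condition siRNA screen.

    With ``use_rendered_images`` the per-well images are rendered and
    segmented (slow; exercises the imaging chain); otherwise hit calling
    runs on the generators' ground-truth adhesion areas, which isolates
    the statistics.  Control wells provide the DMSO reference sample.
    """
    thresholds = thresholds or screen_stats.HitThresholds()
    if len(layout) == 0:
        empty = screen_stats.summarize_screen([])
        return {
            "calls": [], "summary": empty, "hit_table": hit_table([]),
            "gene_truth": pd.DataFrame(), "control_gene": None,
        }
    dataset = synthetic.generate_screen_dataset(
        layout, effects, seed=seed,
        images_per_well=images_per_well,
        adhesions_per_image=adhesions_per_image,
        base_config=base_config,
        render=use_rendered_images,
    )
    if use_rendered_images:
        from fadynamics import morphometrics

        frames = []
        for well_id, sets in dataset.images.items():
            meta = dataset.wells.set_index("well_id").loc[well_id]
            images = [
                {"nuclei": s.nuclei, "paxillin": s.paxillin, "vinculin": s.vinculin}
                for s in sets
            ]
            recs, _ = morphometrics.run_well(
                images, pixel_size_um=sets[0].config.pixel_size_um,
                well=well_id, condition=meta["condition"],
            )
            recs["gene"] = meta["gene"]
            recs["is_control"] = meta["is_control"]
            frames.append(recs)
        table = pd.concat(frames, ignore_index=True)
        # hit calling uses the vinculin channel
        table = table[table.channel == "vinculin"]
        area_col = "area_um2"
    else:
        table = dataset.truth_areas.merge(
            dataset.wells[["well_id", "is_control"]], on="well_id"
        )
        area_col = "area_um2"

    areas: dict[str, dict[str, np.ndarray]] = {}
    for (gene, cond), grp in table.groupby(["gene", "condition"]):
        areas.setdefault(gene, {})[cond] = grp[area_col].to_numpy()
    controls = dataset.wells.loc[dataset.wells.is_control, "gene"].unique()
    if len(controls) == 0:
        raise ValueError("layout contains no control wells")
    control_gene = str(controls[0])

    calls, summary = screen_stats.call_screen(
        areas, control_gene=control_gene, thresholds=thresholds, deselect=deselect
    )
    table_out = hit_table(calls)
    result = {
        "calls": calls,
        "summary": summary,
        "hit_table": table_out,
        "gene_truth": dataset.gene_truth,
        "control_gene": control_gene,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table_out.to_csv(out_dir / "hits.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        write_manifest(
            out_dir,
            config={
                "thresholds": dataclasses.asdict(thresholds),
                "adhesions_per_image": adhesions_per_image,
                "images_per_well": images_per_well,
                "use_rendered_images": use_rendered_images,
                "deselect": list(deselect),
            },
            seeds={"screen": seed},
            counts={"genes": len(calls), "adhesion_rows": len(table)},
            outputs=["hits.csv", "summary.json"],
        )
    return result


def run_tfm(
    condition_configs: Mapping[str, synthetic.PillarSimConfig],
    spec: tfm.PillarSpec | None = None,
    top_fraction: float = 0.05,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate and analyse pillar movies for one or more conditions.

    Per condition: generate the movie, run the detection → grid →
    tracking → force pipeline, and fit the force-autocorrelation
    half-time.  Conditions sharing a frame interval are compared
    pairwise with the extra-sum-of-squares F-test (mismatched intervals
    are refused) and Welch's t-test on per-pillar mean forces.
    """
    spec = spec or tfm.PillarSpec()
    per_condition: dict[str, dict] = {}
    for name, cfg in condition_configs.items():
        movie = synthetic.generate_pillar_movie(cfg)
        res = tfm.analyze_pillar_movie(
            movie.pillar_movie, movie.actin_movie, spec=spec,
            pixel_size_um=cfg.pixel_size_um,
            frame_interval_min=cfg.frame_interval_min,
            top_fraction=top_fraction,
        )
        res["frame_interval_min"] = cfg.frame_interval_min
        res["config"] = cfg
        per_condition[name] = res

    comparisons = []
    names = list(per_condition)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ra, rb = per_condition[a], per_condition[b]
            if ra["frame_interval_min"] != rb["frame_interval_min"]:
                comparisons.append({
                    "condition_a": a, "condition_b": b,
                    "refused": "frame intervals differ",
                })
                continue
            entry: dict = {"condition_a": a, "condition_b": b}
            if "autocorr" in ra and "autocorr" in rb:
                entry["halftime"] = tfm.compare_halftimes(
                    ra["autocorr"], rb["autocorr"]
                )
            if "summary" in ra and "summary" in rb:
                fa = ra["summary"]["per_pillar_mean_force"]
                fb = rb["summary"]["per_pillar_mean_force"]
                if fa.size >= 3 and fb.size >= 3:
                    entry["force"] = tfm.compare_forces(fa, fb)
            comparisons.append(entry)

    result = {"conditions": per_condition, "comparisons": comparisons}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary_json = {}
        for name, res in per_condition.items():
            entry = {
                "n_tracks": len(res["tracks"]),
                "n_full_length": res["n_full_length"],
                "fraction_full_length": res["fraction_full_length"],
                "grid_pitch_um": res["grid"].pitch_um,
                "grid_rotation_deg": res["grid"].rotation_deg,
            }
            if "autocorr" in res:
                fit = res["autocorr"]
                entry["halftime_min"] = fit.halftime_min
                entry["amplitude"] = fit.amplitude
                entry["decay_rate_per_min"] = fit.decay_rate
            summary_json[name] = entry
        with open(out_dir / "tfm_summary.json", "w") as fh:
            json.dump({"conditions": summary_json,
                       "comparisons": _jsonable(comparisons)}, fh, indent=2)
        write_manifest(
            out_dir,
            config={name: dataclasses.asdict(cfg)
                    for name, cfg in condition_configs.items()},
            seeds={name: cfg.seed for name, cfg in condition_configs.items()},
            counts={name: len(res["tracks"]) for name, res in per_condition.items()},
            outputs=["tfm_summary.json"],
        )
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
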