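"""End-to-end workflows tying profiling, scoring and evaluation together."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import rms
from rms.profiles import (
    EndCountProfile,
    count_ends,
    load_profiles,
    save_profile,
)
from rms.scoring import compute_score, parse_score_spec, save_tracks
from rms.evaluation import (
    SiteAnnotation,
    label_positions,
    load_annotation,
    pool_labels,
    roc_mcc,
    save_annotation,
)
from rms.simulate import SimConfig, simulate_profile, simulate_reads

logger = logging.getLogger(__name__)

DEFAULT_SCORES = ("mean2", "a2", "methscore2")


def _write_manifest(out_dir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["package_version"] = rms.__version__
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(
    out_dir,
    profile_path=None,
    bam_path=None,
    annotation_path=None,
    score_specs: Sequence[str] = DEFAULT_SCORES,
    positive: str = "Nm",
    exclude_psi: bool = False,
    max_len_3p: int = 40,
    min_mapq: int = 0,
) -> dict:
    """Profile -> scores -> evaluation, writing all artifacts + a manifest.

    Input is either a profile TSV (possibly multi-reference) or a
    SAM/BAM; detection scores are then evaluated against the annotation
    (Nm positive, pseudouridine/other modified negative unless
    ``exclude_psi``). Returns the JSON-ready summary, keyed by score spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if (profile_path is None) == (bam_path is None):
        raise ValueError("provide exactly one of profile_path or bam_path")
    try:
        if profile_path is not None:
            profiles = load_profiles(profile_path)
        else:
            profiles = {
                None: count_ends(bam_path, max_len_3p=max_len_3p, min_mapq=min_mapq)
            }
            profiles = {p.ref_name: p for p in profiles.values()}
            save_profile(list(profiles.values()), out_dir / "profile.tsv")
    except Exception as exc:
        raise RuntimeError(f"profile stage failed: {exc}") from exc

    try:
        tracks_by_spec = {
            spec: [
                compute_score(prof, *parse_score_spec(spec))
                for prof in profiles.values()
            ]
            for spec in score_specs
        }
        all_tracks = [t for tracks in tracks_by_spec.values() for t in tracks]
        save_tracks(all_tracks, out_dir / "scores.tsv")
    except Exception as exc:
        raise RuntimeError(f"scoring stage failed: {exc}") from exc

    summary: dict = {"scores": {}}
    if annotation_path is not None:
        try:
            annotation = load_annotation(annotation_path)
            exclude = ("psi",) if exclude_psi else ()
            for spec, tracks in tracks_by_spec.items():
                labeled = pool_labels(
                    label_positions(t, annotation, exclude=exclude) for t in tracks
                )
                result = roc_mcc(labeled, positive=positive)
                result.save(
                    roc_path=out_dir / f"roc_{spec}.tsv",
                    json_path=None,
                )
                summary["scores"][spec] = result.summary()
                summary["scores"][spec]["excluded_sites"] = len(
                    labeled.attrs.get("excluded_sites", [])
                )
        except Exception as exc:
            raise RuntimeError(f"evaluation stage failed: {exc}") from exc
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(
        out_dir,
        {
            "command": "pipeline",
            "profile": profile_path,
            "bam": bam_path,
            "annotation": annotation_path,
            "scores": list(score_specs),
            "positive": positive,
            "exclude_psi": exclude_psi,
            "max_len_3p": max_len_3p,
            "min_mapq": min_mapq,
        },
    )
    return summary


#: Miniature three-reference scenario standing in for the 18S/28S/5.8S
#: rRNA trio (synthetic lengths 120/300/60, site counts scaled down).
FIXTURE_REFS = (
    ("SSU_mini", 120, ((25, 1.0), (40, 0.9), (57, 1.0), (83, 0.8), (101, 1.0)), (33, 70)),
    (
        "LSU_mini",
        300,
        (
            (31, 1.0),
            (64, 1.0),
            (92, 0.7),
            (120, 1.0),
            (155, 0.9),
            (188, 1.0),
            (222, 0.6),
            (260, 1.0),
        ),
        (48, 135, 205, 275),
    ),
    ("rRNA5_8S_mini", 60, ((22, 1.0), (41, 1.0)), ()),
)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a deterministic miniature dataset exercising every stage.

    Emits a multi-reference profile TSV, the matching annotation, and a
    SAM + FASTA read fixture for the first reference, plus a manifest
    with the per-reference read tallies. Deterministic under ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=len(FIXTURE_REFS) + 1)
    profiles = []
    annotations = []
    totals = {}
    for (name, length, nm_sites, psi_sites), child in zip(FIXTURE_REFS, child_seeds):
        config = SimConfig(
            ref_length=length,
            seed=int(child),
            nm_sites=nm_sites,
            psi_sites=psi_sites,
            ref_name=name,
        )
        profile, truth = simulate_profile(config)
        profiles.append(profile)
        annotations.append(truth.annotation.sites)
        totals[name] = {
            "count5_total": int(profile.count5.sum()),
            "count3_total": int(profile.count3.sum()),
        }
    save_profile(profiles, out_dir / "profiles.tsv")
    annotation = SiteAnnotation(pd.concat(annotations, ignore_index=True))
    save_annotation(annotation, out_dir / "annotation.tsv")

    name, length, nm_sites, psi_sites = FIXTURE_REFS[0]
    reads_config = SimConfig(
        ref_length=length,
        seed=int(child_seeds[-1]),
        coverage=100.0,
        nm_sites=nm_sites,
        psi_sites=psi_sites,
        ref_name=name,
    )
    reads = simulate_reads(reads_config, out_dir)
    totals["reads"] = {
        "n_reads": reads.n_reads,
        "sam": reads.sam_path.name,
        "fasta": reads.fasta_path.name,
        "count5_total": int(reads.expected.count5.sum()),
        "count3_total": int(reads.expected.count3.sum()),
    }
    manifest = {
        "command": "fixtures",
        "seed": seed,
        "references": [
            {
                "name": name,
                "length": length,
                "n_nm": len(nm),
                "n_psi": len(psi),
            }
            for name, length, nm, psi in FIXTURE_REFS
        ],
        "totals": totals,
    }
    _write_manifest(out_dir, manifest)
    return manifest
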