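"""Orchestration of the full three-phase analysis.

Stages run in order — extract → timing → responsiveness → consistency →
classify — each writing its CSV/JSON outputs to the output directory, with a
combined machine-readable ``report.json`` and human-readable ``report.md``
at the end.  All randomness flows from a single root seed, split per stage,
so a rerun with identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import labeled_signatures, repeated_split_eval
from .consistency import signature_correlations, signature_matrix, standardize_columns
from .features import build_utterance_series, feature_table, MatchCounter
from .lexicons import builtin_lexicons, load_lexicon_tsv, load_liwc_dic
from .responsiveness import (
    ResponsivenessConfig,
    aggregate_graphs,
    analyze_responsiveness,
    links_table,
)
from .timing import contrasts_table, timing_contrasts
from .transcripts import Corpus, read_corpus

log = logging.getLogger("dyadlang")

STAGES = ("extract", "timing", "responsiveness", "consistency", "classify")


@dataclass
class PipelineConfig:
    corpus_path: str | None = None  # directory or transcripts file
    metadata_path: str | None = None
    format: str = "csv"
    lexicon_path: str | None = None  # .dic (LIWC dialect) or .tsv; None -> built-ins
    out_dir: str = "dyadlang_out"
    alpha: float = 0.05
    responsiveness: ResponsivenessConfig = field(default_factory=ResponsivenessConfig)
    n_repeats: int = 1000
    seed: int = 0
    stages: tuple[str, ...] = STAGES


@dataclass
class RunReport:
    config: dict
    corpus_summary: dict
    stage_outputs: dict[str, list[str]]
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "corpus_summary": self.corpus_summary,
            "stage_outputs": self.stage_outputs,
        }


def load_lexicons(path: str | None):
    if path is None:
        return builtin_lexicons()
    p = Path(path)
    if p.suffix == ".dic":
        return load_liwc_dic(p)
    return load_lexicon_tsv(p)


def resolve_corpus_paths(corpus_path: str, metadata_path: str | None, fmt: str):
    p = Path(corpus_path)
    if p.is_dir():
        ext = "csv" if fmt == "csv" else "json"
        return p / f"transcripts.{ext}", p / f"metadata.{ext}"
    if metadata_path is None:
        raise FileNotFoundError("metadata path required when corpus is a file")
    return p, Path(metadata_path)


def run_pipeline(cfg: PipelineConfig, corpus: Corpus | None = None) -> RunReport:
    """Run the configured stages; returns the combined run report.

    ``corpus`` may be passed directly (e.g. fresh from the synthetic
    generator); otherwise it is read from ``cfg.corpus_path``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if corpus is None:
        tpath, mpath = resolve_corpus_paths(cfg.corpus_path, cfg.metadata_path, cfg.format)
        corpus = read_corpus(tpath, mpath, format=cfg.format)
    counter = MatchCounter(load_lexicons(cfg.lexicon_path))
    fatal = [i for i in corpus.issues if i.severity == "error"]
    for issue in corpus.issues:
        log.warning("corpus issue [%s] %s (%s)", issue.severity, issue.message,
                    issue.location)

    seeds = np.random.SeedSequence(cfg.seed).spawn(len(STAGES))
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
                  zip(STAGES, seeds)}
    outputs: dict[str, list[str]] = {}
    summary: dict = {
        "n_sessions": len(corpus.sessions),
        "n_primary": corpus.primary_count,
        "n_secondary": corpus.secondary_count,
        "n_issues": len(corpus.issues),
        "n_fatal_issues": len(fatal),
        "seed": cfg.seed,
    }

    def done(stage: str, paths: list[Path]) -> None:
        # names are stored relative to out_dir so identically-seeded runs are
        # byte-identical regardless of where they are written
        outputs[stage] = [p.name for p in paths]
        log.info("stage %s wrote %d file(s)", stage, len(paths))

    if "extract" in cfg.stages:
        ft = feature_table(corpus, counter)
        path = out / "features.csv"
        ft.to_csv(path, index=False)
        done("extract", [path])

    if "timing" in cfg.stages:
        results, labels = timing_contrasts(corpus, counter, alpha=cfg.alpha)
        path = out / "timing_contrasts.csv"
        contrasts_table(results, labels).to_csv(path, index=False)
        summary["timing"] = {
            "n_contrasts": len(results),
            "n_significant": sum(r.significant for r in results),
        }
        done("timing", [path])

    if "responsiveness" in cfg.stages:
        series = [
            build_utterance_series(s, counter) for s in corpus.primary_sessions
        ]
        reports, graphs = analyze_responsiveness(series, cfg.responsiveness)
        import pandas as pd

        spath = out / "screen_report.csv"
        pd.DataFrame(
            [
                {
                    "session_id": r.session_id,
                    "included": r.included,
                    "reason": r.reason,
                    "offending": ";".join(r.offending),
                }
                for r in reports
            ]
        ).to_csv(spath, index=False)
        lpath = out / "links.csv"
        links_table(graphs).to_csv(lpath, index=False)
        apath = out / "aggregate.csv"
        if graphs:
            aggregate_graphs(graphs).to_csv(apath, index=False)
        else:
            apath.write_text("source,target,count,mean_rho,n_positive,n_negative\n")
        n_links = sum(len(g.links) for g in graphs)
        for r in reports:
            if not r.included:
                log.info("session %s excluded: %s (%s)", r.session_id, r.reason,
                         ",".join(r.offending))
        summary["responsiveness"] = {
            "n_candidates": len(series),
            "n_included": sum(r.included for r in reports),
            "n_excluded": sum(not r.included for r in reports),
            "exclusion_reasons": {
                reason: sum(1 for r in reports if r.reason == reason)
                for reason in sorted({r.reason for r in reports if not r.included})
            },
            "n_significant_links": n_links,
            "mean_links_per_dyad": (
                n_links / len(graphs) if graphs else float("nan")
            ),
        }
        done("responsiveness", [spath, lpath, apath])

    sig = None
    if "consistency" in cfg.stages or "classify" in cfg.stages:
        sig = standardize_columns(signature_matrix(corpus, counter))

    if "consistency" in cfg.stages:
        res = signature_correlations(sig)
        ppath = out / "signature_pairs.csv"
        res.to_frame().to_csv(ppath, index=False)
        jpath = out / "consistency_summary.json"
        jpath.write_text(json.dumps(res.summary(), indent=2, sort_keys=True))
        summary["consistency"] = res.summary()
        done("consistency", [ppath, jpath])

    if "classify" in cfg.stages:
        paths = []
        summary["classification"] = {}
        for task in ("diagnosis", "severity"):
            data = labeled_signatures(sig, corpus, task)
            if data.X.shape[0] < 10 or np.unique(data.y).size < 2:
                log.warning("classification task %s skipped: insufficient data", task)
                summary["classification"][task] = {"skipped": True}
                continue
            ev = repeated_split_eval(
                data, n_repeats=cfg.n_repeats, seed=stage_seed["classify"]
            )
            jpath = out / f"classification_{task}.json"
            jpath.write_text(json.dumps(ev.summary(), indent=2, sort_keys=True))
            cpath = out / f"classification_{task}_repeats.csv"
            ev.to_frame().to_csv(cpath, index=False)
            summary["classification"][task] = ev.summary()
            paths += [jpath, cpath]
        done("classify", paths)

    cfg_dict = {
        "corpus_path": cfg.corpus_path,
        "metadata_path": cfg.metadata_path,
        "format": cfg.format,
        "lexicon_path": cfg.lexicon_path,
        "alpha": cfg.alpha,
        "responsiveness": vars(cfg.responsiveness) | {},
        "n_repeats": cfg.n_repeats,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
    }
    report = RunReport(
        config=cfg_dict, corpus_summary=summary, stage_outputs=outputs
    )
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True)
    )
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: RunReport) -> str:
    s = report.corpus_summary
    lines = [
        "# dyadlang run report",
        "",
        f"- sessions: {s['n_sessions']} ({s['n_primary']} primary, "
        f"{s['n_secondary']} secondary)",
        f"- corpus issues: {s['n_issues']} ({s['n_fatal_issues']} fatal)",
        f"- seed: {s['seed']}",
        "",
    ]
    if "timing" in s:
        t = s["timing"]
        lines.append(
            f"- timing: {t['n_significant']}/{t['n_contrasts']} contrasts "
            "significant after FDR"
        )
    if "responsiveness" in s:
        r = s["responsiveness"]
        lines.append(
            f"- responsiveness: {r['n_included']} dyads analyzed "
            f"({r['n_excluded']} excluded), {r['n_significant_links']} significant "
            f"links, {r['mean_links_per_dyad']:.2f} per dyad"
        )
    if "consistency" in s:
        c = s["consistency"]
        lines.append(
            f"- consistency: mean within r = {c['mean_within']:.3f}, mean between "
            f"r = {c['mean_between']:.3f}, Welch t = {c['t']:.2f} (p = {c['p']:.2g})"
        )
    for task, c in s.get("classification", {}).items():
        if c.get("skipped"):
            lines.append(f"- classification [{task}]: skipped")
        else:
            lines.append(
                f"- classification [{task}]: accuracy {c['mean_model_accuracy']:.3f} "
                f"vs chance {c['mean_chance_accuracy']:.3f} "
                f"(p = {c['empirical_p']:.3f})"
            )
    lines.append("")
    lines.append("## Outputs")
    for stage, files in report.stage_outputs.items():
        for f in files:
            lines.append(f"- {stage}: {f}")
    lines.append("")
    return "\n".join(lines)
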