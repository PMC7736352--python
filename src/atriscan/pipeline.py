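"""End-to-end drivers behind the command-line interface.

``run_screen`` takes a query proteome plus either a homolog database
FASTA (in-house alignment route) or a BLAST tabular file (parsed
route) — never both, because raw alignment scores and bit scores rank
differently — and produces the per-protein NTE report with amphipathic
annotation. ``run_memsig`` censuses one or more genomes (real predictor
files or the built-in rule predictors), fits per-group confidence
ellipses over a reference panel, and classifies every genome.

Reports are written as TSV plus a JSON mirror that embeds the run
parameters, so a report is sufficient to reproduce itself.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignParams, search
from .amphipathic import MomentParams, read_secondary_structure, scan_nte
from .memsig import (
    EllipseModel,
    classify_genome,
    ellipse_boundary,
    fit_reference_ellipse,
    genome_signature,
)
from .nte import NteCall, ScreenParams, call_nte, filter_and_rank
from .predictors import predict_proteome
from .seq_io import (
    parse_blast_tab,
    parse_sp_predictions,
    parse_tm_predictions,
    read_fasta,
)

logger = logging.getLogger("atriscan")


class UsageError(ValueError):
    """Bad invocation/configuration (CLI exit code 2)."""


@dataclass
class ScreenConfig:
    query_fasta: str
    db_fasta: str | None = None
    blast_tab: str | None = None
    out_dir: str = "."
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    moment_params: MomentParams = field(default_factory=MomentParams)
    secondary_structure: str | None = None
    seed: int = 0


def _params_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (v if not isinstance(v, (dict, frozenset)) else sorted(v) if isinstance(v, frozenset) else v) for k, v in d.items()}


def _call_row(call: NteCall) -> dict:
    amph = call.amphipathic
    return {
        "query_id": call.query_id,
        "query_length": call.query_length,
        "n_hits_retained": call.n_hits_retained,
        "min_query_start": call.min_query_start if call.min_query_start is not None else "",
        "nte_length": call.nte_length,
        "is_nte": call.is_nte,
        "status": call.status,
        "conserved_in": ",".join(call.conserved_in),
        "amphipathic": "" if amph is None else amph.is_amphipathic,
        "mu_h": "" if amph is None else round(amph.mu_h, 4),
    }


def run_screen(config: ScreenConfig) -> pd.DataFrame:
    """Run the NTE screen end to end; returns the report table.

    Writes ``screen_report.tsv`` and ``screen_report.json`` under
    ``config.out_dir``.
    """
    if (config.db_fasta is None) == (config.blast_tab is None):
        raise UsageError(
            "provide exactly one homolog source: --db-fasta (in-house "
            "alignment) or --blast-tab (parsed hits); mixing score scales "
            "is not supported"
        )
    queries = read_fasta(config.query_fasta)
    params = config.screen_params
    ss_by_protein = (
        read_secondary_structure(config.secondary_structure)
        if config.secondary_structure
        else {}
    )

    hits_by_query: dict[str, list] = {q.protein_id: [] for q in queries}
    if config.blast_tab is not None:
        for h in parse_blast_tab(config.blast_tab, queries.lengths()):
            hits_by_query[h.query_id].append(h)
    else:
        db = read_fasta(config.db_fasta)
        for q in queries:
            hits_by_query[q.protein_id] = search(
                q.protein_id, q.sequence, db, config.align_params
            )

    rows = []
    for q in queries:
        retained = filter_and_rank(hits_by_query[q.protein_id], params)
        call = call_nte(q, retained, params)
        if call.is_nte and call.nte_length >= 4:
            nte_seq = q.sequence[: call.nte_length]
            ss = ss_by_protein.get(q.protein_id)
            ss_nte = ss[: call.nte_length] if ss else None
            call = dataclasses.replace(
                call, amphipathic=scan_nte(nte_seq, config.moment_params, ss_nte)
            )
        rows.append(_call_row(call))
    report = pd.DataFrame(rows)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "screen_report.tsv", sep="\t", index=False)
    payload = {
        "tool": "atriscan",
        "version": __version__,
        "subcommand": "screen",
        "hit_source": "blast_tab" if config.blast_tab else "builtin_aligner",
        "seed": config.seed,
        "screen_params": _params_dict(params),
        "align_params": _params_dict(config.align_params),
        "moment_params": {
            k: v for k, v in _params_dict(config.moment_params).items() if k != "scale"
        },
        "calls": rows,
    }
    (out / "screen_report.json").write_text(json.dumps(payload, indent=1))
    logger.info("screen: %d queries, %d NTE calls", len(rows), int(report["is_nte"].sum()) if len(report) else 0)
    return report


@dataclass
class MemsigConfig:
    genome_fastas: list[str]
    out_dir: str = "."
    tm_files: dict[str, str] = field(default_factory=dict)       # genome_id -> path
    sp_v4_files: dict[str, str] = field(default_factory=dict)
    sp_v5_files: dict[str, str] = field(default_factory=dict)
    builtin_predictors: bool = False
    panel_tsv: str | None = None
    levels: tuple[float, ...] = (0.95, 0.999)
    robust: bool = False
    seed: int = 0


def _census_one(fasta: str, config: MemsigConfig):
    proteome = read_fasta(fasta)
    gid = proteome.genome_id
    if config.builtin_predictors:
        tm, v4, v5 = predict_proteome(proteome)
        predictor = "builtin"
    else:
        try:
            tm = parse_tm_predictions(config.tm_files[gid])
            v4 = parse_sp_predictions(config.sp_v4_files[gid], "v4like")
            v5 = parse_sp_predictions(config.sp_v5_files[gid], "v5like")
        except KeyError as exc:
            raise UsageError(
                f"no predictor files for genome {gid!r} (missing {exc.args[0]!r}); "
                "supply them or pass builtin_predictors"
            ) from None
        predictor = "external"
    sig = genome_signature(proteome, tm, v4, v5)
    return sig, predictor


def run_memsig(config: MemsigConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Census genomes, fit panel ellipses, classify; returns (signatures, outliers).

    The reference panel TSV needs columns ``genome_id``, ``frac_tm_pct``,
    ``sec_ratio`` and optionally ``group``; one ellipse model is fitted
    per group and every input genome is classified against each model.
    Writes ``signatures.tsv``, ``outlier_report.tsv``,
    ``outlier_report.json`` and per-group ellipse boundary polylines.
    """
    if not config.genome_fastas:
        raise UsageError("no genome FASTA files given")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sig_rows, sigs = [], []
    for fasta in config.genome_fastas:
        sig, predictor = _census_one(fasta, config)
        sigs.append(sig)
        ratio = sig.sec_ratio
        sig_rows.append(
            {
                "genome_id": sig.genome_id,
                "frac_tm_pct": sig.frac_tm_pct,
                "frac_sec_v4_pct": sig.frac_sec_v4_pct,
                "frac_sec_v5_pct": sig.frac_sec_v5_pct,
                "sec_ratio": "" if ratio is None else ratio,
                "predictor": predictor,
            }
        )
        if ratio is None:
            logger.warning("genome %s has zero strict-regime Sec calls; ratio undefined", sig.genome_id)
    signatures = pd.DataFrame(sig_rows)
    signatures.to_csv(out / "signatures.tsv", sep="\t", index=False)

    outlier_rows: list[dict] = []
    if config.panel_tsv is not None:
        panel = pd.read_csv(config.panel_tsv, sep="\t")
        required = {"genome_id", "frac_tm_pct", "sec_ratio"}
        if not required.issubset(panel.columns):
            raise UsageError(f"panel TSV must have columns {sorted(required)}")
        if "group" not in panel.columns:
            panel["group"] = "reference"
        models: dict[str, EllipseModel] = {}
        for group, sub in panel.groupby("group"):
            if len(sub) < 3:
                logger.warning("panel group %r has < 3 genomes; skipped", group)
                continue
            models[group] = fit_reference_ellipse(
                list(zip(sub["frac_tm_pct"], sub["sec_ratio"])),
                levels=config.levels,
                robust=config.robust,
            )
            boundary = pd.DataFrame(
                [
                    {"group": group, "level": lv, "frac_tm_pct": x, "sec_ratio": y}
                    for lv in config.levels
                    for x, y in ellipse_boundary(models[group], lv)
                ]
            )
            boundary.to_csv(out / f"ellipse_{group}.tsv", sep="\t", index=False)
        for sig in sigs:
            for group, model in models.items():
                sub = panel[panel["group"] == group]
                ref = [
                    type(sig)(
                        genome_id=str(r.genome_id),
                        frac_tm_pct=float(r.frac_tm_pct),
                        frac_sec_v4_pct=1.0,
                        frac_sec_v5_pct=float(r.sec_ratio),
                    )
                    for r in sub.itertuples()
                ]
                rep = classify_genome(sig, model, ref)
                row = {
                    "genome_id": sig.genome_id,
                    "reference_group": group,
                    "mahalanobis_sq": "" if rep.mahalanobis_sq is None else rep.mahalanobis_sq,
                    "frac_tm_percentile": rep.frac_tm_percentile,
                    "reason": rep.reason,
                }
                for lv in config.levels:
                    row[f"inside_{lv}"] = "" if rep.inside[lv] is None else rep.inside[lv]
                outlier_rows.append(row)
    outliers = pd.DataFrame(outlier_rows)
    outliers.to_csv(out / "outlier_report.tsv", sep="\t", index=False)
    payload = {
        "tool": "atriscan",
        "version": __version__,
        "subcommand": "memsig",
        "seed": config.seed,
        "levels": list(config.levels),
        "robust": config.robust,
        "signatures": sig_rows,
        "outliers": outlier_rows,
    }
    (out / "outlier_report.json").write_text(json.dumps(payload, indent=1))
    return signatures, outliers
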