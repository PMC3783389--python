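"""End-to-end pipeline wiring: microarray -> prediction -> degradome (-> qPCR).

A :class:`RunConfig` names every input and parameter; :func:`run_all`
executes the stages in order, writing ``diff.tsv``, ``targets.tsv``,
``events.tsv``, per-transcript t-plot tables and a machine-readable run
manifest.  Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import degradome as deg
from . import microarray as ma
from . import qpcr as qp
from .formats import (
    read_ct_table,
    read_fasta,
    read_signal_table,
    read_tags,
    write_target_table,
)
from .target_prediction import ScoringScheme, predict_targets

log = logging.getLogger("mircleave")


@dataclass(frozen=True)
class _SiteRef:
    """Adapter giving a target-table row the site interface degradome needs."""

    transcript_id: str
    cleavage_position: int
    row: object


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Serializable to a simple ``key = value`` text file; unset optional
    inputs skip their stage.
    """

    signals: str | None = None
    mirnas: str | None = None
    transcripts: str | None = None
    tags: str | None = None
    ct: str | None = None
    out_dir: str = "mircleave-out"
    cutoff: float = 4.0
    core_start: int = 2
    core_end: int = 13
    max_bulges: int = 1
    preset: str = "methods"
    min_reads: int = 1
    qpcr_reference: str = "5.8S"
    qpcr_calibrator: str = "calibrator"
    qpcr_test: str = "test"
    seed: int = 0

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            core_range=(self.core_start, self.core_end),
            max_bulges=self.max_bulges,
            cutoff=self.cutoff,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` config file (``#`` comments allowed)."""
        cfg = cls()
        types = cls.__dataclass_fields__
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            for key, value in asdict(self).items():
                if value is not None:
                    fh.write(f"{key} = {value}\n")


def run_all(config: RunConfig) -> Path:
    """Execute every configured stage; returns the artifact directory.

    microarray and the predict/degradome chain run when their inputs are
    set; qPCR runs when Ct data is given.  A manifest with version,
    parameters and per-stage outputs is always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        if config.signals:
            stage = "microarray"
            log.info("stage %s: %s", stage, config.signals)
            try:
                p_thr, lr_thr = ma.THRESHOLD_PRESETS[config.preset]
                rows = read_signal_table(config.signals)
                called, summary, _fit = ma.analyze(
                    rows, p_threshold=p_thr, log2_threshold=lr_thr
                )
                with open(out / "diff.tsv", "w", newline="\n") as fh:
                    fh.write("mirna\tsignal_a\tsignal_b\tlog2_ratio\tp_value\tcall\n")
                    for r in called:
                        fh.write(
                            f"{r.mirna}\t{r.signal_a:.6g}\t{r.signal_b:.6g}\t"
                            f"{r.log2_ratio:.4f}\t{r.p_value:.4g}\t{r.call}\n"
                        )
                manifest["stages"][stage] = {
                    "n_up": summary.n_up,
                    "n_down": summary.n_down,
                    "n_families": summary.n_families,
                    "output": "diff.tsv",
                }
            except Exception as exc:
                raise StageError(stage, exc) from exc

        targets = None
        transcripts = None
        if config.mirnas and config.transcripts:
            stage = "predict"
            log.info("stage %s: %s vs %s", stage, config.mirnas, config.transcripts)
            try:
                mirnas = read_fasta(config.mirnas)
                transcripts = read_fasta(config.transcripts)
                targets = predict_targets(mirnas, transcripts, config.scheme())
                write_target_table(targets, out / "targets.tsv")
                manifest["stages"][stage] = {"n_sites": len(targets), "output": "targets.tsv"}
            except Exception as exc:
                raise StageError(stage, exc) from exc

        if config.tags and targets is not None and transcripts is not None:
            stage = "degradome"
            log.info("stage %s: %s", stage, config.tags)
            try:
                tags = read_tags(config.tags)
                profiles = deg.map_tags(tags, transcripts)
                sites = [
                    _SiteRef(transcript_id=t.transcript, cleavage_position=t.cleavage_site, row=t)
                    for t in targets
                ]
                events = deg.validate_targets(sites, profiles, min_reads=config.min_reads)
                with open(out / "events.tsv", "w", newline="\n") as fh:
                    fh.write(
                        "mirna\ttranscript\trange\tcleavage_site\tscore\t"
                        "site_count\ttranscript_max\ttranscript_median\tcategory\n"
                    )
                    for ev in events:
                        row = ev.site.row
                        fh.write(
                            f"{row.mirna}\t{row.transcript}\t{row.start}-{row.end}\t"
                            f"{row.cleavage_site}\t{row.score:g}\t{ev.site_count}\t"
                            f"{ev.transcript_max}\t{ev.transcript_median:g}\t{ev.category}\n"
                        )
                tplot_dir = out / "tplots"
                tplot_dir.mkdir(exist_ok=True)
                marked: dict[str, set[int]] = {}
                for ev in events:
                    marked.setdefault(ev.site.transcript_id, set()).add(ev.site.cleavage_position)
                for tid, profile in sorted(profiles.items()):
                    deg.write_t_plot_table(
                        profile, tplot_dir / f"{tid}.tsv", marked.get(tid, ())
                    )
                manifest["stages"][stage] = {
                    "n_events": len(events),
                    "n_profiles": len(profiles),
                    "output": "events.tsv",
                }
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, exc) from exc

        if config.ct:
            stage = "qpcr"
            log.info("stage %s: %s", stage, config.ct)
            try:
                table = read_ct_table(config.ct)
                design = qp.QpcrDesign(
                    test_sample=config.qpcr_test,
                    calibrator_sample=config.qpcr_calibrator,
                    reference_assay=config.qpcr_reference,
                )
                results = qp.summarize_replicates(table, design)
                qp.write_ratio_table(results, out / "ratios.tsv")
                manifest["stages"][stage] = {"n_targets": len(results), "output": "ratios.tsv"}
            except Exception as exc:
                raise StageError(stage, exc) from exc
    except StageError:
        manifest["incomplete"] = True
        _write_manifest()
        raise
    _write_manifest()
    return out
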