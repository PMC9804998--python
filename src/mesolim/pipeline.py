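"""Pipeline orchestration: ingest -> standardise -> QC -> limitation/stats.

``run_pipeline`` runs the stages in fixed order over a :class:`RunConfig`
and writes a result bundle (tidy CSV/JSON tables plus a manifest recording
package version, config hash, seed and temperature-response choice) so a
rerun with the same config and seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .limitation import fit_limitation_curve, pft_limitation_ranges
from .qc import FilterThresholds, run_qc
from .records import ANALYSIS_PFTS, read_dataset, standardize_units_frame, write_dataset
from .temperature import derive_gas_exchange, load_response
from .traitstats import dunn_test, fit_gamma_glm

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the row context."""


@dataclass
class RunConfig:
    input: str | Path
    out_dir: str | Path
    schema: dict[str, str] | None = None
    tresponse: str = "tobacco"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    analyses: tuple[str, ...] = ("limitation", "glm", "dunn")
    exclude_ids: tuple[int, ...] = ()
    n_bootstrap: int = 1000
    seed: int = 0

    def config_hash(self) -> str:
        # paths excluded: the hash identifies the analysis settings, not
        # where the bundle lands on disk
        payload = dataclasses.asdict(self)
        payload.pop("input")
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and serialise the result bundle.

    Returns a mapping of artifact name -> written path.  Artifacts:
    ``records`` (standardised rows), ``qc_report``, ``limitation_fit``,
    ``pft_ranges``, ``glm_table``, ``dunn_table``, ``manifest``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    df, parse_log = _stage("ingest")(read_dataset)(config.input, config.schema)
    resp = load_response(config.tresponse)
    df = _stage("standardize")(standardize_units_frame)(df)
    df = _stage("standardize")(derive_gas_exchange)(df, resp)
    retained, report = _stage("qc")(run_qc)(df, config.thresholds)

    parse_log.to_json(out_dir / "parse_log.json")
    written["parse_log"] = out_dir / "parse_log.json"
    write_dataset(retained, out_dir / "records.csv")
    written["records"] = out_dir / "records.csv"
    report.to_json(out_dir / "qc_report.json")
    written["qc_report"] = out_dir / "qc_report.json"

    analysed = retained[retained["pft"].isin([p.value for p in ANALYSIS_PFTS])]

    if "limitation" in config.analyses:
        pairs = analysed.dropna(subset=["gm_25", "An", "Anp"])
        lm = _stage("limitation")(
            lambda d: (d["Anp"] - d["An"]) / d["Anp"] * 100.0
        )(pairs)
        fit = _stage("limitation")(fit_limitation_curve)(
            pairs["gm_25"], lm,
            exclude=[i for i in config.exclude_ids if i in pairs.index],
            n_bootstrap=config.n_bootstrap, random_state=config.seed,
        )
        (out_dir / "limitation_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        written["limitation_fit"] = out_dir / "limitation_fit.json"
        ranges = pft_limitation_ranges(
            pairs[["pft", "gm_25"]], fit
        )
        ranges.to_csv(out_dir / "pft_ranges.csv", index=False)
        written["pft_ranges"] = out_dir / "pft_ranges.csv"

    if "glm" in config.analyses:
        sub = analysed.dropna(subset=["gm_25", "Sc", "Tcw"])
        glm = _stage("glm")(fit_gamma_glm)(
            sub["gm_25"], sub["Sc"], sub["Tcw"], study_id=sub["study_id"],
        )
        glm.to_frame().to_csv(out_dir / "glm_table.csv", index=False)
        written["glm_table"] = out_dir / "glm_table.csv"

    if "dunn" in config.analyses:
        sub = analysed.dropna(subset=["gm_25"])
        table = _stage("dunn")(dunn_test)(sub["gm_25"], sub["pft"].astype(str))
        table.to_csv(out_dir / "dunn_table.csv", index=False)
        written["dunn_table"] = out_dir / "dunn_table.csv"

    manifest = {
        "package": "mesolim",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tresponse": config.tresponse,
        "n_input": int(report.n_input),
        "n_retained": int(report.n_retained),
        "n_excluded_by": report.n_excluded_by,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = out_dir / "manifest.json"
    return written
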