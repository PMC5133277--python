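"""Subprocess bridge to the lme4 fitting worker.

The estimation itself is delegated to lme4/glmer through ``Rscript``: data
and a job description are written to a temporary directory, the packaged
worker script fits the requested model(s), and results come back as JSON.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from importlib import resources
from pathlib import Path

import pandas as pd


class FitBackendError(RuntimeError):
    """The R fitting backend failed or is unavailable."""


def _worker_script() -> Path:
    with resources.as_file(resources.files("mtverify") / "r" / "fit_mixed.R") as p:
        return Path(p)


def ensure_rscript() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise FitBackendError(
            "Rscript not found on PATH; mixed-model fitting requires R with lme4"
        )
    return exe


def run_mixed_fits(
    data: pd.DataFrame,
    *,
    response: str,
    fixed: list[str],
    random: list[dict],
    family: str = "gaussian",
    reml: bool = True,
    prune: bool = True,
    batch: str | None = None,
    timeout_s: float = 3600.0,
) -> list[dict]:
    """Fit one model (or one per level of ``batch``) and return raw results.

    ``random`` is a list of ``{"group": column, "term": column-or-"1"}``
    entries; each term gets its own variance (uncorrelated slopes).  Raises
    :class:`FitBackendError` on backend failure; per-dataset estimation
    errors come back as ``{"error": ...}`` entries.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unsupported family {family!r}")
    exe = ensure_rscript()
    cols = {response, *fixed}
    cols.update(r["group"] for r in random)
    cols.update(r["term"] for r in random if r["term"] != "1")
    if batch:
        cols.add(batch)
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")

    with tempfile.TemporaryDirectory(prefix="mtverify_fit_") as tmp:
        tmp_path = Path(tmp)
        data_csv = tmp_path / "data.csv"
        out_json = tmp_path / "out.json"
        job_json = tmp_path / "job.json"
        data[sorted(cols)].to_csv(data_csv, index=False)
        job = {
            "data": str(data_csv),
            "out": str(out_json),
            "response": response,
            "family": family,
            "fixed": list(fixed),
            "random": list(random),
            "reml": bool(reml),
            "prune": bool(prune),
            "batch": batch,
        }
        job_json.write_text(json.dumps(job))
        proc = subprocess.run(
            [exe, "--vanilla", str(_worker_script()), str(job_json)],
            capture_output=True,
            text=True,
            timeout=timeout_s,
        )
        if proc.returncode != 0 or not out_json.exists():
            tail = (proc.stderr or "")[-2000:]
            raise FitBackendError(f"R fitting worker failed (exit {proc.returncode}):\n{tail}")
        return json.loads(out_json.read_text())
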