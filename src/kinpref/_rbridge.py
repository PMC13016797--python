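"""Subprocess bridge to the R negative-binomial GLMM worker.

Each call batches any number of fit jobs into a single Rscript invocation
(the interpreter and glmmTMB load dominate wall time, the fits themselves
are fast).  Jobs and results travel as JSON; data as one CSV with a
``job_id`` column.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["NBJob", "run_nb_glmm_jobs", "RBridgeError"]


class RBridgeError(RuntimeError):
    pass


@dataclass
class NBJob:
    """One negative-binomial GLMM fit request."""

    id: str
    response: str
    fixed: Sequence[str]
    random: Sequence[str]
    data: pd.DataFrame
    interactions: bool = False
    alpha: float = 0.05
    lr_tests: Sequence[str] = field(default_factory=tuple)
    factor_levels: Mapping[str, Sequence[str]] = field(default_factory=dict)


def _script_path() -> Path:
    return Path(resources.files("kinpref") / "glmm_fit.R")


def run_nb_glmm_jobs(jobs: Sequence[NBJob], timeout_s: float = 1800.0) -> dict[str, dict]:
    """Run a batch of NB-GLMM jobs in one Rscript call; return raw results."""
    if not jobs:
        return {}
    rscript = shutil.which("Rscript")
    if rscript is None:
        raise RBridgeError("Rscript not found on PATH; negative-binomial GLMMs need R")
    ids = [j.id for j in jobs]
    if len(set(ids)) != len(ids):
        raise ValueError("job ids must be unique")

    with tempfile.TemporaryDirectory(prefix="kinpref_glmm_") as tmp:
        tmp_path = Path(tmp)
        frames = []
        for j in jobs:
            df = j.data.copy()
            df["job_id"] = j.id
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(tmp_path / "data.csv", index=False)
        spec = [
            {
                "id": j.id,
                "response": j.response,
                "fixed": list(j.fixed),
                "random": list(j.random),
                "interactions": bool(j.interactions),
                "alpha": j.alpha,
                "lr_tests": list(j.lr_tests),
                "factor_levels": {k: list(v) for k, v in j.factor_levels.items()},
            }
            for j in jobs
        ]
        (tmp_path / "jobs.json").write_text(json.dumps(spec))
        out_path = tmp_path / "out.json"
        proc = subprocess.run(
            [
                rscript,
                "--vanilla",
                str(_script_path()),
                str(tmp_path / "jobs.json"),
                str(tmp_path / "data.csv"),
                str(out_path),
            ],
            capture_output=True,
            text=True,
            timeout=timeout_s,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RBridgeError(
                f"glmm worker failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        results = json.loads(out_path.read_text())
    for jid, res in results.items():
        if not res.get("ok", False):
            raise RBridgeError(f"job {jid}: {res.get('error', 'unknown R error')}")
    return results
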