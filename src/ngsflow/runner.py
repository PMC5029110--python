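"""Execute workflow steps with restart/skip semantics and per-job logs.

Each sample of a :class:`~ngsflow.sysargs.SysArgs` step is one external
process.  Runs are restartable: samples whose expected outputs already exist
non-empty are skipped unless ``force`` is set, so re-issuing a run after a
crash completes only the missing samples.  Every job's stdout/stderr is
captured to ``<logdir>/<step>/<sample>.log`` and a line-delimited JSON status
registry (``status.jsonl``) is appended after each sample, giving a
database-like, machine-readable run history.

Failed jobs leave their partial outputs renamed with a ``.failed`` suffix so
completion checks never mistake them for success.  There are no automatic
retries; rerunning is an explicit user action.

Parallel execution uses a local process pool with the same contract as the
serial runner; results are reported in targets row order regardless of
completion order.  Cluster schedulers are out of scope — the parallel map is
the extension point.
"""

from __future__ import annotations

import concurrent.futures
import json
import os
import shutil
import subprocess
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

from .sysargs import ConfigurationError, SysArgs, completed

__all__ = ["RunResult", "run_serial", "run_parallel", "status"]


@dataclass
class RunResult:
    """Outcome of one sample of one step.

    ``state`` is ``done`` (exit 0 and all outputs non-empty), ``skipped``
    (outputs already present, no process launched) or ``failed``.
    """

    sample_name: str
    state: str
    exit_code: Optional[int]
    log_path: str
    started: float
    finished: float


def _step_logdir(logdir: str | Path, step_name: str) -> Path:
    d = Path(logdir) / step_name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _registry_path(logdir: str | Path, step_name: str) -> Path:
    return _step_logdir(logdir, step_name) / "status.jsonl"


def _append_record(registry: Path, result: RunResult) -> None:
    # single os.write of one line: atomic under concurrent appenders (O_APPEND)
    line = (json.dumps(asdict(result)) + "\n").encode()
    fd = os.open(registry, os.O_WRONLY | os.O_CREAT | os.O_APPEND, 0o644)
    try:
        os.write(fd, line)
    finally:
        os.close(fd)


def _check_software(step: SysArgs) -> None:
    exe = step.argvs[0][0] if step.argvs else step.software
    if os.path.sep in exe:
        if not (os.path.isfile(exe) and os.access(exe, os.X_OK)):
            raise ConfigurationError(f"software not found or not executable: {exe}")
    elif shutil.which(exe) is None:
        raise ConfigurationError(f"software not found on PATH: {exe}")


def _launch_one(argv: list[str], sample: str, outfiles: list[str],
                log_path: str) -> RunResult:
    """Run one job, capture its log, verify outputs; importable for pickling."""
    started = time.time()
    for out in outfiles:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
    with open(log_path, "w", encoding="utf-8") as log:
        log.write(f"# command: {' '.join(argv)}\n")
        log.flush()
        try:
            proc = subprocess.run(argv, stdout=log, stderr=subprocess.STDOUT)
            exit_code: Optional[int] = proc.returncode
        except OSError as exc:  # launch failure of this one job
            log.write(f"# launch error: {exc}\n")
            exit_code = None
    ok = exit_code == 0 and all(
        os.path.isfile(p) and os.path.getsize(p) > 0 for p in outfiles
    )
    if not ok:
        for p in outfiles:  # quarantine partial outputs
            if os.path.exists(p):
                os.replace(p, p + ".failed")
    return RunResult(
        sample_name=sample,
        state="done" if ok else "failed",
        exit_code=exit_code,
        log_path=log_path,
        started=started,
        finished=time.time(),
    )


def _job_plan(step: SysArgs, logdir: str | Path, force: bool):
    """Yield (index, skip?) decisions in row order, before any launch."""
    done_flags = completed(step)
    for i, sample in enumerate(step.sample_names):
        yield i, (done_flags[i] and not force)


def run_serial(step: SysArgs, force: bool = False,
               logdir: str | Path = "logs") -> list[RunResult]:
    """Run a step one sample at a time, in targets row order.

    Samples already completed are skipped unless ``force``; a failing sample
    is recorded and the run continues with the remaining ones.
    """
    _check_software(step)
    stepdir = _step_logdir(logdir, step.step_name)
    registry = _registry_path(logdir, step.step_name)
    results: list[RunResult] = []
    for i, skip in _job_plan(step, logdir, force):
        sample = step.sample_names[i]
        if skip:
            now = time.time()
            res = RunResult(sample, "skipped", None,
                            str(stepdir / f"{sample}.log"), now, now)
        else:
            res = _launch_one(step.argvs[i], sample, step.outfiles[i],
                              str(stepdir / f"{sample}.log"))
        _append_record(registry, res)
        results.append(res)
    return results


def run_parallel(step: SysArgs, workers: int, force: bool = False,
                 logdir: str | Path = "logs") -> list[RunResult]:
    """Run a step via a local process pool; contract identical to serial.

    Results are returned in targets row order regardless of completion order.
    A crashed worker marks only its own sample failed.
    """
    if workers < 1:
        raise ConfigurationError("workers must be >= 1")
    _check_software(step)
    stepdir = _step_logdir(logdir, step.step_name)
    registry = _registry_path(logdir, step.step_name)
    results: dict[int, RunResult] = {}
    to_launch: list[int] = []
    for i, skip in _job_plan(step, logdir, force):
        sample = step.sample_names[i]
        if skip:
            now = time.time()
            results[i] = RunResult(sample, "skipped", None,
                                   str(stepdir / f"{sample}.log"), now, now)
            _append_record(registry, results[i])
        else:
            to_launch.append(i)
    if to_launch:
        with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
            futs = {
                pool.submit(
                    _launch_one, step.argvs[i], step.sample_names[i],
                    step.outfiles[i], str(stepdir / f"{step.sample_names[i]}.log"),
                ): i
                for i in to_launch
            }
            for fut in concurrent.futures.as_completed(futs):
                i = futs[fut]
                try:
                    res = fut.result()
                except Exception as exc:  # worker crash: only this sample fails
                    now = time.time()
                    res = RunResult(step.sample_names[i], "failed", None,
                                    str(stepdir / f"{step.sample_names[i]}.log"),
                                    now, now)
                    with open(res.log_path, "a", encoding="utf-8") as log:
                        log.write(f"# worker crash: {exc}\n")
                _append_record(registry, res)
                results[i] = res
    return [results[i] for i in range(len(step.sample_names))]


def status(logdir: str | Path, step_name: str) -> list[RunResult]:
    """Return the last recorded result per sample from a step's registry.

    An absent registry yields an empty list; corrupt lines are skipped with a
    warning on stderr.
    """
    registry = Path(logdir) / step_name / "status.jsonl"
    if not registry.is_file():
        return []
    latest: dict[str, RunResult] = {}
    with open(registry, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                res = RunResult(**rec)
            except (json.JSONDecodeError, TypeError) as exc:
                import sys
                print(f"warning: {registry}:{lineno}: skipping corrupt record "
                      f"({exc})", file=sys.stderr)
                continue
            latest[res.sample_name] = res  # last record wins, insertion order kept
    return list(latest.values())
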