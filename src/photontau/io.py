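"""Plain-text readers and writers.

Canonical trace format — a delimited text file, locale-independent
(decimal points), one microtime per row:

    # photontau trace
    # units: ns
    # pulse_period: 25.0
    microtime_ns
    4.0613
    0.9271
    ...

Times are nanoseconds everywhere; the header must declare both the unit
and the pulse period. Results are a JSON document (summaries, seeds and
the full configuration needed to reproduce the run) plus a CSV chain file
of retained lifetime samples.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .inference import PosteriorReport, PosteriorSamples, SpeciesEstimates
from .model import PhotonTrace
from .simulate import GroundTruth

__all__ = [
    "TraceFormatError",
    "read_microtimes",
    "write_microtimes",
    "write_truth",
    "write_results",
    "read_results",
]

_HEADER_COLUMN = "microtime_ns"


class TraceFormatError(ValueError):
    """Raised when a trace file violates the expected text format."""


def write_microtimes(trace: PhotonTrace, path) -> None:
    """Write a trace in the canonical text format (see module docstring)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# photontau trace\n")
        fh.write("# units: ns\n")
        fh.write(f"# pulse_period: {trace.pulse_period!r}\n")
        fh.write(_HEADER_COLUMN + "\n")
        for t in trace.microtimes:
            fh.write(f"{float(t)!r}\n")


def read_microtimes(path) -> PhotonTrace:
    """Parse a canonical trace file into a validated :class:`PhotonTrace`.

    Format errors (missing unit/pulse-period header, non-numeric rows)
    raise :class:`TraceFormatError` naming the offending line.
    """
    path = Path(path)
    units = None
    pulse_period = None
    values: list[float] = []
    saw_column = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key == "units":
                        units = val.strip().lower()
                        if units != "ns":
                            raise TraceFormatError(
                                f"{path}:{lineno}: unsupported units {units!r} "
                                "(only 'ns' is supported)"
                            )
                    elif key == "pulse_period":
                        try:
                            pulse_period = float(val)
                        except ValueError:
                            raise TraceFormatError(
                                f"{path}:{lineno}: pulse_period is not numeric: {val.strip()!r}"
                            ) from None
                continue
            if not saw_column:
                if line != _HEADER_COLUMN:
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected column header "
                        f"{_HEADER_COLUMN!r}, found {line!r}"
                    )
                saw_column = True
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise TraceFormatError(
                    f"{path}:{lineno}: non-numeric microtime row {line!r}"
                ) from None
    if units is None:
        raise TraceFormatError(f"{path}: missing '# units: ns' header line")
    if pulse_period is None:
        raise TraceFormatError(f"{path}: missing '# pulse_period:' header line")
    if not values:
        raise TraceFormatError(f"{path}: trace file contains no microtimes")
    return PhotonTrace(microtimes=np.asarray(values), pulse_period=pulse_period)


def write_truth(truth: GroundTruth, path) -> None:
    """Write simulator ground truth as CSV (one row per photon).

    Columns: 0-based species tag (-1 = background), excited-state dwell,
    IRF error term (both ns, empty for background photons), background
    flag.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("tag,excited_dwell_ns,error_term_ns,is_background\n")
        for tag, dw, er, bg in zip(
            truth.tags, truth.excited_dwells, truth.error_terms, truth.is_background
        ):
            dw_s = "" if np.isnan(dw) else repr(float(dw))
            er_s = "" if np.isnan(er) else repr(float(er))
            fh.write(f"{int(tag)},{dw_s},{er_s},{int(bg)}\n")


def _estimates_to_dict(est: SpeciesEstimates) -> dict:
    return {
        "mean": [float(x) for x in est.mean],
        "median": [float(x) for x in est.median],
        "ci_low": [float(x) for x in est.ci_low],
        "ci_high": [float(x) for x in est.ci_high],
    }


def _estimates_from_dict(d: dict) -> SpeciesEstimates:
    return SpeciesEstimates(
        mean=np.asarray(d["mean"]),
        median=np.asarray(d["median"]),
        ci_low=np.asarray(d["ci_low"]),
        ci_high=np.asarray(d["ci_high"]),
    )


def write_results(report: PosteriorReport, samples: PosteriorSamples, path) -> dict:
    """Write a machine-readable results file and a lifetime chain file.

    ``path`` is the results JSON path; the chain CSV (one row per retained
    sweep: every component's lifetime in ns plus the occupied-species
    count) is written next to it with suffix ``.chain.csv``. The JSON
    records the sampler seed, priors and settings, so any run can be
    reproduced bit-exactly. Returns the results dictionary.
    """
    path = Path(path)
    doc = {
        "n_photons": report.n_photons,
        "n_retained": report.n_retained,
        "modal_species_count": report.modal_species_count,
        "low_information": bool(report.low_information),
        "species_count_posterior": {
            str(k): float(v) for k, v in sorted(report.species_count_posterior.items())
        },
        "lifetime_ns": _estimates_to_dict(report.lifetime_estimates),
        "fraction": _estimates_to_dict(report.fraction_estimates),
        "acceptance_rate": float(samples.acceptance_rate),
        "settings": dataclasses.asdict(samples.settings),
        "priors": dataclasses.asdict(samples.priors),
        "chain_file": path.with_suffix(".chain.csv").name,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    chain_path = path.with_suffix(".chain.csv")
    m = samples.inverse_lifetimes.shape[1]
    header = ",".join(f"tau_{i + 1}_ns" for i in range(m)) + ",occupied_count"
    with chain_path.open("w") as fh:
        fh.write(header + "\n")
        for row, occ in zip(samples.lifetimes, samples.occupied_counts):
            fh.write(",".join(repr(float(x)) for x in row) + f",{int(occ)}\n")
    return doc


def read_results(path) -> tuple[PosteriorReport, dict]:
    """Read back a results JSON; returns the report and the raw document."""
    doc = json.loads(Path(path).read_text())
    report = PosteriorReport(
        species_count_posterior={int(k): v for k, v in doc["species_count_posterior"].items()},
        modal_species_count=int(doc["modal_species_count"]),
        lifetime_estimates=_estimates_from_dict(doc["lifetime_ns"]),
        fraction_estimates=_estimates_from_dict(doc["fraction"]),
        n_photons=int(doc["n_photons"]),
        n_retained=int(doc["n_retained"]),
        low_information=bool(doc["low_information"]),
    )
    return report, doc
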