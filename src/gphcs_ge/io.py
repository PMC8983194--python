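"""Dataset files, bundled fixtures and report serialization.

A dataset file stores the censoring design (n, m, k, T, planned removals R)
and the observed failure times y.  JSON is the canonical format; a simple
``field,value`` CSV dialect is also accepted.  Times are stored as decimal
strings so printed data round-trip bit-exactly.  On load, the case
bookkeeping (D*, R*, R_tau, T*) is always recomputed from the plan and
observed times; any stored bookkeeping is cross-checked and a mismatch is
an error.

The bundled ``ball_bearings`` fixtures are the classic deep-groove
ball-bearing endurance data (failure times in millions of revolutions),
censored under three thresholds of the same progressive plan
(n=23, m=15, k=9, R=(2,0^7,3,0^5,3)): T=50 terminates before the 9th
failure, T=80 between the 9th and 15th, T=110 after the 15th — one fixture
per termination case.
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .censoring import CensoringPlan, GPHCSample, sample_from_observed

__all__ = [
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "load_ball_bearings",
    "ReportBundle",
    "write_report",
]

_FIXTURES = {1: "ball_bearings_scheme1.json", 2: "ball_bearings_scheme2.json",
             3: "ball_bearings_scheme3.json"}


class DatasetError(ValueError):
    """A dataset file is malformed or internally inconsistent."""


def _parse_payload(payload: dict, source: str) -> tuple:
    required = {"n", "m", "k", "T", "R", "y"}
    missing = required - payload.keys()
    if missing:
        raise DatasetError(f"{source}: missing fields {sorted(missing)}")
    try:
        plan = CensoringPlan(
            n=int(payload["n"]), m=int(payload["m"]), k=int(payload["k"]),
            R=tuple(int(r) for r in payload["R"]), T=float(payload["T"]),
        )
    except ValueError as err:
        raise DatasetError(f"{source}: invalid plan: {err}") from err
    y = [float(v) for v in payload["y"]]
    try:
        sample = sample_from_observed(y, plan)
    except ValueError as err:
        raise DatasetError(f"{source}: invalid observations: {err}") from err

    # cross-check any stored bookkeeping against the recomputed values
    checks = {
        "D_star": (sample.D_star, lambda v: int(v)),
        "R_star": (sample.R_star, lambda v: tuple(int(r) for r in v)),
        "R_tau": (sample.R_tau, lambda v: int(v)),
        "T_star": (sample.T_star, lambda v: float(v)),
        "case": (sample.case.value, lambda v: str(v)),
    }
    for key, (computed, conv) in checks.items():
        if key in payload and conv(payload[key]) != computed:
            raise DatasetError(
                f"{source}: stored {key}={payload[key]!r} contradicts the "
                f"recomputed value {computed!r}"
            )
    return plan, sample


def read_dataset(path) -> tuple[CensoringPlan, GPHCSample]:
    """Read a dataset file (JSON or ``field,value`` CSV) and validate it."""
    path = str(path)
    text = open(path, encoding="utf-8").read()
    if path.endswith(".json") or text.lstrip().startswith("{"):
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as err:
            raise DatasetError(f"{path}: not valid JSON: {err}") from err
    else:
        payload = {}
        for row in csv.reader(text.splitlines()):
            if not row or row[0].startswith("#"):
                continue
            key, values = row[0].strip(), [v for v in row[1:] if v != ""]
            if not values:
                raise DatasetError(f"{path}: field {key!r} has no value")
            payload[key] = values if key in ("R", "y", "R_star") else values[0]
    return _parse_payload(payload, path)


def write_dataset(plan: CensoringPlan, sample: GPHCSample, path) -> None:
    """Write a dataset as canonical JSON with times as decimal strings."""
    payload = {
        "n": plan.n, "m": plan.m, "k": plan.k, "T": repr(plan.T),
        "R": list(plan.R),
        "y": [repr(v) for v in sample.y],
        "D_star": sample.D_star, "R_star": list(sample.R_star),
        "R_tau": sample.R_tau, "T_star": repr(sample.T_star),
        "case": sample.case.value,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_ball_bearings(scheme: int) -> tuple[CensoringPlan, GPHCSample]:
    """Load one of the three bundled ball-bearing censored datasets.

    ``scheme`` 1, 2 or 3 selects the threshold T = 50, 80 or 110 million
    revolutions.
    """
    if scheme not in _FIXTURES:
        raise ValueError("scheme must be 1, 2 or 3")
    ref = resources.files("gphcs_ge").joinpath("datasets", _FIXTURES[scheme])
    payload = json.loads(ref.read_text(encoding="utf-8"))
    return _parse_payload(payload, _FIXTURES[scheme])


@dataclass
class ReportBundle:
    """Everything one analysis produced, ready for serialization.

    ``ml`` holds point estimates, the information matrix and intervals;
    ``bayes`` one block per prior with SEL estimates, credible intervals and
    chain diagnostics.  ``provenance`` records seed and software versions.
    """

    input_summary: dict
    ml: dict
    bayes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "ReportBundle":
        for block in [self.ml, *self.bayes]:
            for name, iv in block.get("intervals", {}).items():
                if not iv["lower"] <= iv["point"] <= iv["upper"]:
                    raise ValueError(f"interval {name} does not bracket its point")
        return self

    @staticmethod
    def provenance_stamp(seed=None) -> dict:
        import gphcs_ge

        return {
            "seed": seed,
            "package": "gphcs_ge " + gphcs_ge.__version__,
            "numpy": np.__version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }


def write_report(bundle: ReportBundle, path, format: str = "json") -> None:
    """Serialize a report losslessly (JSON) or as a compact estimates table
    (CSV: one row per estimand, one column block per method and interval)."""
    bundle.validate()
    path = str(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(bundle), fh, indent=1, default=_jsonify)
            fh.write("\n")
        return
    if format != "csv":
        raise ValueError("format must be 'json' or 'csv'")
    methods = ["ML"] + [b.get("label", f"Bayes-{i+1}") for i, b in enumerate(bundle.bayes)]
    blocks = [bundle.ml, *bundle.bayes]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["estimand"] + [f"{m} point" for m in methods]
                   + [f"{m} interval" for m in methods])
        for est in ("alpha", "lambda", "S", "H"):
            row = [est]
            for b in blocks:
                row.append(_fmt(b.get("point", {}).get(est)))
            for b in blocks:
                iv = b.get("intervals", {}).get(est)
                row.append("" if iv is None else f"({_fmt(iv['lower'])}, {_fmt(iv['upper'])})")
            w.writerow(row)


def _fmt(v):
    return "" if v is None else f"{v:.10g}"


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
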