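"""Deterministic report bundles for pipeline runs.

A report is one directory holding the tables a run produced (composition,
morphometry, contacts, coverage, group statistics), the exact thresholds
and parameters used, and a JSON manifest.  Regeneration from identical
inputs and configuration is byte-identical, so reports can be diffed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .classify import ClassificationThresholds, TypeCall, calls_table
from .mercs import ContactParams, ContactSite, CoverageRecord, contacts_table, coverage_table
from .morphometry import MorphometryRecord, morphometry_table
from .stats import TestResult


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return obj


def build_report(
    out_dir: str | Path,
    *,
    morphometry: Sequence[MorphometryRecord] | None = None,
    calls: Sequence[TypeCall] | None = None,
    composition: pd.DataFrame | None = None,
    contacts: Sequence[ContactSite] | None = None,
    coverages: Sequence[CoverageRecord] | None = None,
    grouped: pd.DataFrame | None = None,
    tests: Sequence[TestResult] | None = None,
    thresholds: ClassificationThresholds | None = None,
    contact_params: ContactParams | None = None,
    preset_name: str | None = None,
    seed: int | None = None,
    extra_config: Mapping[str, Any] | None = None,
) -> dict:
    """Write every available section and a manifest; return the manifest.

    Sections not supplied are recorded as absent in the manifest rather
    than written empty, so a partial run (e.g. no ER volume, hence no
    contacts) is distinguishable from a run that found nothing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sections: dict[str, str | None] = {}

    def _write(name: str, df: pd.DataFrame | None, index: bool = False) -> None:
        if df is None:
            sections[name] = None
            return
        path = out / f"{name}.csv"
        df.to_csv(path, index=index)
        sections[name] = path.name

    _write("morphometry", morphometry_table(morphometry) if morphometry is not None else None)
    _write("type_calls", calls_table(calls) if calls is not None else None)
    _write("composition", composition, index=True)
    _write("contacts", contacts_table(contacts) if contacts is not None else None)
    _write("coverage", coverage_table(coverages) if coverages is not None else None)
    _write("mercs_by_type", grouped, index=True)
    if tests is not None:
        _write(
            "stats",
            pd.DataFrame(
                [
                    {
                        "test": t.test,
                        "groups": " vs ".join(t.groups),
                        "direction": t.direction or "",
                        "statistic": t.statistic,
                        "df": "/".join(str(d) for d in t.df),
                        "p_value": t.p_value,
                        "flags": ";".join(t.flags),
                    }
                    for t in tests
                ]
            ),
        )
    else:
        sections["stats"] = None

    manifest = {
        "sections": sections,
        "n_mitochondria": len(morphometry) if morphometry is not None else None,
        "n_contacts": len(contacts) if contacts is not None else None,
        "preset": preset_name,
        "thresholds": _as_jsonable(thresholds),
        "contact_params": _as_jsonable(contact_params),
        "seed": seed,
        "config": dict(extra_config or {}),
        "complete": all(v is not None for v in sections.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
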