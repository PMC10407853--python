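"""Pipeline orchestration: config parsing, stage sequencing, reports.

Runs filter -> classify -> summarize (-> turn-type fitting when an
atom mapping is configured) over one or more conformer-ensemble files
and writes diffable CSV/JSON reports (no timestamps in payloads).
Anchor configurations arrive as YAML with 1-based atom indices, the
convention of the SDF records they refer to.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .mimicry import (
    AnchorSet,
    MotifCriteria,
    filter_energy_window,
    label_conformer,
    summarize,
)
from .structio import Ensemble, read_pdb, read_sdf, read_xyz
from .turnfit import fit_turn_types

__all__ = ["RunConfig", "run_pipeline", "load_anchor_config", "read_ensemble"]

log = logging.getLogger("foldmimic")

_ANCHOR_FIELDS = {
    "helix": 3, "three10": 3, "turn_quartet": 4, "d_alpha_pair": 2,
    "nhb": 2, "nha": 2, "nhb_acceptors": None, "nha_acceptors": None,
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    inputs: List[Path]
    anchor_config: Path
    output_dir: Path
    energy_window: float = 10.0
    criteria_overrides: Dict[str, object] = field(default_factory=dict)
    seed: int = 0
    verbose: int = 0


def _to_zero_based(name: str, values: Sequence[int]) -> Tuple[int, ...]:
    out = []
    for v in values:
        if not isinstance(v, int) or v < 1:
            raise ValueError(f"anchor {name!r}: indices are 1-based positive integers, got {v!r}")
        out.append(v - 1)
    return tuple(out)


def load_anchor_config(path) -> Tuple[str, AnchorSet, MotifCriteria, Optional[list]]:
    """Parse a YAML anchor config.

    Returns (compound id, anchors, criteria, turn-fit mapping or None).
    Anchor atom indices in the file are 1-based; the mapping pairs a
    1-based conformer atom with a [1-based residue, atom name] template
    position.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "anchors" not in raw:
        raise ValueError(f"anchor config {path} must contain an 'anchors' section")
    compound = str(raw.get("compound", Path(path).stem))
    kw: Dict[str, object] = {}
    for name, vals in raw["anchors"].items():
        if name not in _ANCHOR_FIELDS:
            raise ValueError(f"unknown anchor field {name!r}")
        expected = _ANCHOR_FIELDS[name]
        if expected is not None and len(vals) != expected:
            raise ValueError(f"anchor {name!r} needs {expected} indices, got {len(vals)}")
        kw[name] = _to_zero_based(name, vals)
    anchors = AnchorSet(**kw)
    overrides = raw.get("criteria", {}) or {}
    valid = {f.name for f in dataclasses.fields(MotifCriteria)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown criteria override(s): {sorted(unknown)}")
    for key in ("helix_ref", "three10_ref"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    criteria = MotifCriteria(**overrides)
    mapping = None
    if "mapping" in raw and raw["mapping"]:
        mapping = [
            (int(atom) - 1, (int(res) - 1, str(name)))
            for atom, (res, name) in (
                (entry[0], entry[1]) for entry in raw["mapping"]
            )
        ]
    return compound, anchors, criteria, mapping


def read_ensemble(path, energy_field: str = "E_kcal") -> Ensemble:
    """Dispatch on extension: .sdf, .xyz, .pdb."""
    suffix = Path(path).suffix.lower()
    readers = {".sdf": lambda p: read_sdf(p, energy_field), ".xyz": read_xyz, ".pdb": read_pdb}
    if suffix not in readers:
        raise ValueError(f"unsupported ensemble format {suffix!r} (expected .sdf/.xyz/.pdb)")
    return readers[suffix](path)


def run_pipeline(cfg: RunConfig) -> Dict[str, Path]:
    """Execute the classification pipeline over every configured input.

    Writes ``summary.csv`` (one row per compound), ``labels.json``
    (per-conformer records) and, when a turn-fit mapping is present,
    ``turnfit.csv``.  All results are computed before anything is
    written, so partial outputs are never left behind.  Returns the
    mapping of report name -> path.
    """
    logging.basicConfig(level=logging.DEBUG if cfg.verbose else logging.INFO)
    if not Path(cfg.anchor_config).exists():
        raise FileNotFoundError(f"anchor config not found: {cfg.anchor_config}")
    compound, anchors, criteria, mapping = load_anchor_config(cfg.anchor_config)
    if cfg.criteria_overrides:
        criteria = dataclasses.replace(criteria, **cfg.criteria_overrides)

    summaries, label_rows, fit_rows = [], [], []
    for inp in cfg.inputs:
        ens = read_ensemble(inp)
        name = compound if len(cfg.inputs) == 1 else f"{compound}:{Path(inp).stem}"
        try:
            anchors.validate(ens.molecule)
        except ValueError as exc:
            raise ValueError(f"compound {name}: {exc}") from exc
        log.info("%s: %d conformers read", name, len(ens))
        windowed = filter_energy_window(ens, cfg.energy_window)
        log.info("%s: %d conformers within %.1f kcal/mol", name, len(windowed), cfg.energy_window)
        s = summarize(windowed, anchors, criteria, compound=name)
        summaries.append(s)
        for c in windowed.conformers:
            lab = label_conformer(c, anchors, criteria, windowed.molecule)
            label_rows.append(
                {
                    "compound": name,
                    "conformer": c.id,
                    "energy": c.energy,
                    "is_alpha": lab.is_alpha,
                    "is_beta": lab.is_beta,
                    "is_310": lab.is_310,
                    "d_alpha": lab.d_alpha,
                    "beta_dihedral": lab.beta_dihedral,
                    "c10_present": bool(lab.c10 and lab.c10.present),
                }
            )
            if mapping is not None:
                fit = fit_turn_types(c, mapping)
                fit_rows.append(
                    {"compound": name, "conformer": c.id, "best": fit.best,
                     **{f"rmsd_{t}": r for t, r in fit.rmsd.items()}}
                )

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    summary_df = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "n_conformers": s.n_conformers,
                "pct_beta": s.pct_beta,
                "pct_alpha": s.pct_alpha,
                "pct_310": s.pct_310,
                "global_min": s.global_minimum,
            }
            for s in summaries
        ]
    )
    paths["summary"] = out / "summary.csv"
    summary_df.to_csv(paths["summary"], index=False)
    paths["labels"] = out / "labels.json"
    paths["labels"].write_text(json.dumps(label_rows, indent=1))
    if fit_rows:
        paths["turnfit"] = out / "turnfit.csv"
        pd.DataFrame(fit_rows).to_csv(paths["turnfit"], index=False)
    log.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths
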