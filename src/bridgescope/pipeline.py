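"""Configuration-driven orchestration of analysis stages.

A run is described by a plain YAML/dict config::

    stages:
      - stage: synth_bridge
        seed: 7
        n_frames: 2000
        populations: {GEOMETRY_A: 0.64, GEOMETRY_B: 0.20, OTHER_SALT_BRIDGE: 0.05,
                      N_O_BRIDGE: 0.06, LONG_RANGE: 0.05}
        out: frames.tsv
      - stage: classify
        input: frames.tsv
        arg: 62
        glu: 38
        out: states.tsv
      - stage: summarize
        input: states.tsv
        out: summary.json

    Unknown keys are rejected before anything executes; every seed and
    parameter ends up in the run manifest, so a rerun with the same config is
    byte-identical.
"""

from __future__ import annotations

import json
from importlib.metadata import version
from pathlib import Path

import numpy as np

from .errors import BridgescopeError
from .saltbridge import BridgeCriteria, BridgeState, classify_ensemble, centroid_distance, summarize
from .structure_io import read_frame_table, write_frame_table
from .synthetic_data import gen_bridge_ensemble

__all__ = ["run", "validate_config", "ConfigError"]


class ConfigError(BridgescopeError):
    """The run configuration is malformed."""


_STAGE_KEYS = {
    "synth_bridge": {"stage", "seed", "n_frames", "populations", "jitter_sigma",
                     "out", "labels_out"},
    "classify": {"stage", "input", "arg", "glu", "centroid_cutoff",
                 "no_pair_cutoff", "out"},
    "summarize": {"stage", "input", "out"},
}
_REQUIRED = {
    "synth_bridge": {"seed", "n_frames", "populations", "out"},
    "classify": {"input", "arg", "glu", "out"},
    "summarize": {"input", "out"},
}


def validate_config(config: dict) -> None:
    """Reject unknown keys and missing required keys before execution."""
    if set(config) - {"stages"}:
        raise ConfigError(f"unknown top-level keys: {sorted(set(config) - {'stages'})}")
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config needs a non-empty 'stages' list")
    for i, st in enumerate(stages):
        kind = st.get("stage")
        if kind not in _STAGE_KEYS:
            raise ConfigError(f"stage {i}: unknown stage kind {kind!r}")
        unknown = set(st) - _STAGE_KEYS[kind]
        if unknown:
            raise ConfigError(f"stage {i} ({kind}): unknown keys {sorted(unknown)}")
        missing = _REQUIRED[kind] - set(st)
        if missing:
            raise ConfigError(f"stage {i} ({kind}): missing keys {sorted(missing)}")


def _write_states_tsv(path: Path, ens, labels, pair, criteria) -> int:
    from numpy.linalg import norm

    arg_res, glu_res = pair
    i_ca_a = ens.atom_index(arg_res, "CA")
    i_ca_g = ens.atom_index(glu_res, "CA")
    with path.open("w") as fh:
        fh.write("frame\tlabel\tcentroid_d\tca_d\n")
        for i, lab in enumerate(labels):
            cd = centroid_distance(ens, i, pair, criteria)
            ca = norm(ens.coords[i, i_ca_a] - ens.coords[i, i_ca_g])
            fh.write(f"{int(ens.frame_labels[i])}\t{lab.value}\t{cd:.6f}\t{ca:.6f}\n")
    return len(labels)


def run(config: dict, workdir: str | Path = ".") -> dict:
    """Execute the configured stages in order; return the run manifest.

    On a stage failure the error propagates with the failing stage named;
    outputs of earlier stages are retained.  The manifest (also written to
    ``workdir/manifest.json``) records package version, every stage's
    parameters and output row counts.
    """
    validate_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "bridgescope", "version": version("bridgescope"),
                      "stages": []}
    for i, st in enumerate(config["stages"]):
        kind = st["stage"]
        entry = {"index": i, **st}
        try:
            if kind == "synth_bridge":
                pops = {BridgeState[k]: float(v) for k, v in st["populations"].items()}
                ens, labels = gen_bridge_ensemble(
                    pops, int(st["n_frames"]), int(st["seed"]),
                    jitter_sigma=float(st.get("jitter_sigma", 0.05)),
                )
                write_frame_table(ens, workdir / st["out"])
                if "labels_out" in st:
                    (workdir / st["labels_out"]).write_text(
                        "\n".join(l.value for l in labels) + "\n")
                entry["n_rows"] = ens.n_frames
            elif kind == "classify":
                ens = read_frame_table(workdir / st["input"])
                criteria = BridgeCriteria(
                    centroid_cutoff=float(st.get("centroid_cutoff", 4.0)),
                    no_pair_cutoff=float(st.get("no_pair_cutoff", 4.0)),
                )
                pair = (int(st["arg"]), int(st["glu"]))
                labels = classify_ensemble(ens, pair, criteria)
                entry["n_rows"] = _write_states_tsv(
                    workdir / st["out"], ens, labels, pair, criteria)
            elif kind == "summarize":
                import pandas as pd

                df = pd.read_csv(workdir / st["input"], sep="\t")
                n = len(df)
                fracs = (df["label"].value_counts() / n).to_dict()
                out = {
                    "n_frames": n,
                    "fractions": {s.value: float(fracs.get(s.value, 0.0))
                                  for s in BridgeState},
                    "ca_distance": {
                        lab: {"mean": float(sub["ca_d"].mean()),
                              "sd": float(sub["ca_d"].std(ddof=0))}
                        for lab, sub in df.groupby("label")
                    },
                }
                (workdir / st["out"]).write_text(
                    json.dumps(out, indent=2, sort_keys=True) + "\n")
                entry["n_rows"] = n
        except Exception as exc:
            raise BridgescopeError(f"stage {i} ({kind}) failed: {exc}") from exc
        manifest["stages"].append(entry)
    (workdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
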