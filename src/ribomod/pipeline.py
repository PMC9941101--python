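"""End-to-end orchestration: simulate -> score -> diff -> concordance.

Stages hand data to each other through plain TSV files so every intermediate
is inspectable and individually re-loadable; a run is deterministic given
the master seed, and every output table carries a header recording the
package version, the effective seed and a digest of the parameters plus the
formula variants in effect (flank width, background window/mode, end offset).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import RnaReference, SiteCatalog, read_reference, read_site_catalog
from .concord import concord_table, concordance_summary, read_de_table
from .diff import ScoreMatrix, diff_table, heatmap_matrix
from .hydrapsi import score_catalog_psi
from .rms import score_catalog_rms
from .simulate import (
    HYDRAPSI,
    RMS,
    EndCountProfile,
    ProtocolParams,
    TruthProfile,
    simulate_hydrapsi,
    simulate_rms,
    write_profile,
)

__all__ = [
    "PipelineError",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "run_demo",
    "derive_seed",
    "read_truth",
]


class PipelineError(RuntimeError):
    pass


def derive_seed(master: int, *keys: int) -> int:
    """A stable sub-seed (< 2^31) for one simulation stream."""
    state = np.random.SeedSequence([int(master), *map(int, keys)]).generate_state(1)
    return int(state[0] % (2**31))


def read_truth(path, mod_type: str) -> dict[str, TruthProfile]:
    """Read ``molecule  position  fraction`` TSV into per-molecule truths."""
    df = pd.read_csv(path, sep="\t", comment="#")
    truths: dict[str, TruthProfile] = {}
    for molecule, group in df.groupby("molecule"):
        fractions = dict(zip(group["position"].astype(int), group["fraction"]))
        truths[str(molecule)] = TruthProfile(
            molecule=str(molecule), fractions=fractions, mod_type=mod_type
        )
    return truths


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    seed: int
    reference_fasta: Path
    nm_catalog: Path
    psi_catalog: Path
    conditions: dict  # condition -> {"nm_truth": path, "psi_truth": path}
    replicates: int = 3
    rms_params: dict = field(default_factory=lambda: {"depth": 20000.0})
    hydrapsi_params: dict = field(default_factory=lambda: {"depth": 5000.0})
    flank: int = 6
    window: int = 10
    exclude_self: bool = True
    affected_threshold: float = 0.05
    heatmap_threshold: float = 0.1
    fc_threshold: float = 0.0
    sig_threshold: float = 0.05
    comparisons: list = field(default_factory=list)
    de_table: Path | None = None

    def __post_init__(self) -> None:
        for attr in ("reference_fasta", "nm_catalog", "psi_catalog", "de_table"):
            value = getattr(self, attr)
            if value is None:
                continue
            path = Path(value)
            if not path.exists():
                raise PipelineError(f"{attr}: no such file {path}")
            setattr(self, attr, path)
        for cond, files in self.conditions.items():
            for key, value in files.items():
                path = Path(value)
                if not path.exists():
                    raise PipelineError(f"{cond}/{key}: no such file {path}")
                files[key] = path
        if self.replicates < 1:
            raise PipelineError("replicates must be >= 1")
        for name in ("affected_threshold", "heatmap_threshold", "sig_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if not self.comparisons:
            conds = list(self.conditions)
            self.comparisons = [[conds[0], c] for c in conds[1:]]

    def digest(self) -> str:
        """Digest of the scientific parameters (paths excluded, so two runs
        of the same analysis in different directories share a digest)."""
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if not isinstance(v, (Path, dict)) and k != "comparisons"
        }
        payload["comparisons"] = self.comparisons
        payload["conditions"] = sorted(self.conditions)
        payload["rms_params"] = self.rms_params
        payload["hydrapsi_params"] = self.hydrapsi_params
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _resolve(value):
        return None if value is None else (base / value if not Path(value).is_absolute() else Path(value))

    conditions = {
        cond: {k: _resolve(v) for k, v in files.items()}
        for cond, files in raw["conditions"].items()
    }
    return RunConfig(
        seed=int(raw["seed"]),
        reference_fasta=_resolve(raw["reference_fasta"]),
        nm_catalog=_resolve(raw["nm_catalog"]),
        psi_catalog=_resolve(raw["psi_catalog"]),
        conditions=conditions,
        replicates=int(raw.get("replicates", 3)),
        rms_params=dict(raw.get("rms", {"depth": 20000.0})),
        hydrapsi_params=dict(raw.get("hydrapsi", {"depth": 5000.0})),
        flank=int(raw.get("flank", 6)),
        window=int(raw.get("window", 10)),
        exclude_self=bool(raw.get("exclude_self", True)),
        affected_threshold=float(raw.get("affected_threshold", 0.05)),
        heatmap_threshold=float(raw.get("heatmap_threshold", 0.1)),
        fc_threshold=float(raw.get("fc_threshold", 0.0)),
        sig_threshold=float(raw.get("sig_threshold", 0.05)),
        comparisons=[list(c) for c in raw.get("comparisons", [])],
        de_table=_resolve(raw.get("de_table")),
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# ribomod={__version__} seed={config.seed} digest={config.digest()}\n")
        fh.write(
            f"# methscore=symmetric-flank-mean flank={config.flank} "
            f"psiscore=1-normucount window={config.window} "
            f"background={'leave-one-out' if config.exclude_self else 'plain-mean'} "
            f"end_offset={config.rms_params.get('end_offset', 0)}"
            f"{' ' + extra if extra else ''}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def _simulate_condition(
    config: RunConfig,
    refs: Mapping[str, RnaReference],
    catalog: SiteCatalog,
    truths: Mapping[str, TruthProfile],
    protocol: str,
    cond_index: int,
) -> list[EndCountProfile]:
    raw = config.rms_params if protocol == RMS else config.hydrapsi_params
    proto_index = 0 if protocol == RMS else 1
    profiles: list[EndCountProfile] = []
    for mol_index, molecule in enumerate(catalog.molecules()):
        truth = truths.get(molecule)
        if truth is None:
            raise PipelineError(f"no {protocol} truth supplied for molecule {molecule}")
        params = ProtocolParams(
            protocol=protocol,
            seed=derive_seed(config.seed, cond_index, proto_index, mol_index),
            **raw,
        )
        sim = simulate_rms if protocol == RMS else simulate_hydrapsi
        profiles.extend(sim(refs[molecule], truth, params, config.replicates))
    return profiles


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Run every stage, writing all tables under ``outdir``; returns paths."""
    outdir = Path(outdir)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    refs = read_reference(config.reference_fasta)
    nm_catalog = read_site_catalog(config.nm_catalog, refs)
    psi_catalog = read_site_catalog(config.psi_catalog, refs)

    score_tables: dict[str, pd.DataFrame] = {}
    for cond_index, (condition, files) in enumerate(config.conditions.items()):
        nm_truths = read_truth(files["nm_truth"], "Nm")
        psi_truths = read_truth(files["psi_truth"], "Psi")
        rms_profiles = _simulate_condition(
            config, refs, nm_catalog, nm_truths, RMS, cond_index
        )
        psi_profiles = _simulate_condition(
            config, refs, psi_catalog, psi_truths, HYDRAPSI, cond_index
        )
        for profile in rms_profiles + psi_profiles:
            ppath = (
                outdir
                / "profiles"
                / f"{condition}_{profile.protocol}_{profile.molecule}_{profile.replicate_id}.tsv"
            )
            write_profile(profile, ppath, seed=config.seed)
        nm_scores = score_catalog_rms(rms_profiles, nm_catalog, flank=config.flank)
        psi_scores = score_catalog_psi(
            psi_profiles,
            psi_catalog,
            refs,
            window=config.window,
            exclude_self=config.exclude_self,
        )
        scores = pd.concat([nm_scores, psi_scores], ignore_index=True)
        spath = outdir / f"scores_{condition}.tsv"
        _write_table(scores, spath, config, extra=f"condition={condition}")
        outputs[f"scores_{condition}"] = spath
        score_tables[condition] = scores

    matrix = ScoreMatrix.from_tables(score_tables)
    comparisons: list[tuple[str, pd.DataFrame]] = []
    catalog_all = SiteCatalog.from_sites(tuple(nm_catalog) + tuple(psi_catalog))
    de = read_de_table(config.de_table) if config.de_table else None
    for ref_cond, alt_cond in config.comparisons:
        label = f"{alt_cond}_vs_{ref_cond}"
        table = diff_table(
            matrix,
            ref_cond,
            alt_cond,
            affected_threshold=config.affected_threshold,
            heatmap_threshold=config.heatmap_threshold,
        )
        dpath = outdir / f"diff_{label}.tsv"
        _write_table(table, dpath, config, extra=f"comparison={label}")
        outputs[f"diff_{label}"] = dpath
        comparisons.append((label, table))
        if de is not None:
            calls, report = concord_table(
                table,
                catalog_all,
                de,
                fc_threshold=config.fc_threshold,
                sig_threshold=config.sig_threshold,
            )
            cpath = outdir / f"concordance_{label}.tsv"
            _write_table(report, cpath, config, extra=f"comparison={label}")
            outputs[f"concordance_{label}"] = cpath
            summary = concordance_summary(calls)
            spath = outdir / f"concordance_summary_{label}.tsv"
            _write_table(
                pd.DataFrame([summary]), spath, config, extra=f"comparison={label}"
            )
            outputs[f"concordance_summary_{label}"] = spath

    hm = heatmap_matrix(comparisons)
    hpath = outdir / "heatmap_matrix.tsv"
    _write_table(hm, hpath, config)
    outputs["heatmap_matrix"] = hpath

    log = outdir / "run.log"
    with open(log, "w") as fh:
        fh.write(f"ribomod {__version__}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"digest {config.digest()}\n")
        fh.write(f"conditions {list(config.conditions)}\n")
        fh.write(f"comparisons {config.comparisons}\n")
        fh.write(
            f"scoring flank={config.flank} window={config.window} "
            f"exclude_self={config.exclude_self}\n"
        )
    outputs["log"] = log
    return outputs


def run_demo(outdir, seed: int = 1, replicates: int = 3,
             rms_depth: float = 20000.0, psi_depth: float = 5000.0) -> dict[str, Path]:
    """Materialise the packaged fixtures and run the full pipeline on them."""
    from .fixtures import write_demo_inputs

    outdir = Path(outdir)
    inputs = write_demo_inputs(outdir / "inputs")
    config = RunConfig(
        seed=seed,
        reference_fasta=inputs["reference_fasta"],
        nm_catalog=inputs["nm_catalog"],
        psi_catalog=inputs["psi_catalog"],
        conditions={
            "WT": {
                "nm_truth": inputs["truth_WT_Nm"],
                "psi_truth": inputs["truth_WT_Psi"],
            },
            "FUS_KO": {
                "nm_truth": inputs["truth_FUS_KO_Nm"],
                "psi_truth": inputs["truth_FUS_KO_Psi"],
            },
        },
        replicates=replicates,
        rms_params={"depth": rms_depth},
        hydrapsi_params={"depth": psi_depth},
        comparisons=[["WT", "FUS_KO"]],
        de_table=inputs["de_table"],
    )
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "reference_fasta": str(inputs["reference_fasta"]),
                "nm_catalog": str(inputs["nm_catalog"]),
                "psi_catalog": str(inputs["psi_catalog"]),
                "conditions": {
                    c: {
                        "nm_truth": str(inputs[f"truth_{c}_Nm"]),
                        "psi_truth": str(inputs[f"truth_{c}_Psi"]),
                    }
                    for c in ("WT", "FUS_KO")
                },
                "replicates": replicates,
                "rms": {"depth": rms_depth},
                "hydrapsi": {"depth": psi_depth},
                "comparisons": [["WT", "FUS_KO"]],
                "de_table": str(inputs["de_table"]),
            },
            fh,
        )
    outputs = run_pipeline(config, outdir)
    outputs["config"] = config_path
    outputs.update(inputs)
    return outputs
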