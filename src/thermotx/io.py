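"""On-disk formats: FASTA, PWM count tables, TSV profiles, parameter files.

All tabular outputs are tab-delimited with a single header line; lines
beginning with ``#`` carry metadata and are ignored on read.  Site tables use
BED-flavored columns (construct, start, end, tf, score, strand) with 0-based
half-open intervals.  PWM count tables use a simple labeled layout:
a ``>tf_id`` header, then one labeled row per base giving the number of
observed bases at each position.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .params import ModelConfig, ModelParams, Param, default_config
from .pipeline import Construct, ExpressionProfile
from .pwm import PWM, BindingSite, build_pwm

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pwm_counts",
    "write_pwm_counts",
    "read_profiles",
    "write_profiles",
    "write_site_table",
    "read_params",
    "write_params",
    "RunConfig",
    "load_config",
]


class ConfigError(ValueError):
    """A run configuration failed validation."""


# -- sequences ---------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Record id -> uppercase sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- PWM count tables --------------------------------------------------------

def read_pwm_counts(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> dict[str, PWM]:
    """Read one or many count matrices from a ``>tf_id``-delimited text file.

    Each matrix is four labeled rows (A/C/G/T) of per-position counts.
    """
    matrices: dict[str, dict[str, list[float]]] = {}
    current: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            matrices[current] = {}
            continue
        if current is None:
            current = Path(path).stem
            matrices[current] = {}
        parts = line.replace(":", " ").replace("|", " ").split()
        base = parts[0].upper()
        if base not in "ACGT" or len(base) != 1:
            raise ValueError(f"unexpected row label {parts[0]!r} in {path}")
        matrices[current][base] = [float(v) for v in parts[1:]]
    out = {}
    for tf, rows in matrices.items():
        if set(rows) != set("ACGT"):
            raise ValueError(f"matrix {tf!r} must have rows A, C, G, T")
        counts = np.array([rows[b] for b in "ACGT"]).T  # width x 4
        out[tf] = build_pwm(counts, background=background, pseudocount=pseudocount, tf_id=tf)
    return out


def write_pwm_counts(path: str | Path, counts: dict[str, np.ndarray]) -> None:
    """Write count matrices (width x 4 arrays keyed by TF) to one text file."""
    lines = []
    for tf, mat in counts.items():
        mat = np.asarray(mat)
        lines.append(f">{tf}")
        for b, row in zip("ACGT", mat.T):
            lines.append(b + "\t" + "\t".join(f"{v:g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# -- delimited profile tables ------------------------------------------------

def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a profile table (first column = axis position in % EL)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "position_pct_el"
    return df


def write_profiles(path: str | Path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index_label="position_pct_el")


def write_expression(path: str | Path, profile: ExpressionProfile) -> None:
    write_profiles(
        path,
        pd.DataFrame({"rate": profile.values},
                     index=pd.Index(profile.positions, name="position_pct_el")),
        meta={"construct": profile.construct_id},
    )


# -- site tables -------------------------------------------------------------

def write_site_table(
    path: str | Path, construct_id: str, sites: list[BindingSite]
) -> None:
    df = pd.DataFrame(
        {
            "construct": construct_id,
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "tf": [s.tf_id for s in sites],
            "score": [round(s.score, 6) for s in sites],
            "strand": [s.strand for s in sites],
            "rel_affinity": [round(s.rel_affinity, 9) for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- parameter files ---------------------------------------------------------

def write_params(path: str | Path, params: ModelParams) -> None:
    """Flat key-value parameter file: name value lo hi free scale."""
    lines = ["name\tvalue\tlo\thi\tfree\tscale"]
    for p in params.entries.values():
        lines.append(
            f"{p.name}\t{p.value:.12g}\t{p.lo:g}\t{p.hi:g}\t"
            f"{int(p.free)}\t{p.scale}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path, config: ModelConfig) -> ModelParams:
    params = ModelParams(config=config, entries={})
    for raw in Path(path).read_text().splitlines()[1:]:
        if not raw.strip() or raw.startswith("#"):
            continue
        name, value, lo, hi, free, scale = raw.split("\t")
        params.entries[name] = Param(
            name=name, value=float(value), lo=float(lo), hi=float(hi),
            free=bool(int(free)), scale=scale,
        )
    return params


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration for the command-line interface."""

    sequences: Path
    pwms: Path
    profiles: Path
    out_dir: Path
    observations: Path | None = None
    params_file: Path | None = None
    tss: dict[str, int] = field(default_factory=dict)
    targeted: dict[str, bool] = field(default_factory=dict)
    seed: int = 0
    optimizer: str = "generic_sa"
    budget: int = 50_000
    pseudocount: float = 1.0
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    def model_config(self) -> ModelConfig:
        ids = tuple(sorted(read_fasta(self.sequences)))
        return default_config(
            construct_ids=ids,
            targeted={c: self.targeted.get(c, True) for c in ids},
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every referenced path must exist; every construct in the FASTA needs a
    TSS entry; every roster factor needs a PWM and a profile column.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def _path(key: str, required: bool = True) -> Path | None:
        v = raw.get("paths", {}).get(key)
        if v is None:
            if required:
                raise ConfigError(f"config missing required path {key!r}")
            return None
        p = Path(v)
        if not p.is_absolute():
            p = base / p
        if key != "out_dir" and not p.exists():
            raise ConfigError(f"configured {key} path {p} does not exist")
        return p

    run = raw.get("run", {})
    cfg = RunConfig(
        sequences=_path("sequences"),
        pwms=_path("pwms"),
        profiles=_path("profiles"),
        out_dir=_path("out_dir", required=False) or base / "out",
        observations=_path("observations", required=False),
        params_file=_path("params", required=False),
        tss={str(k): int(v) for k, v in raw.get("tss", {}).items()},
        targeted={str(k): bool(v) for k, v in raw.get("targeted", {}).items()},
        seed=int(run.get("seed", 0)),
        optimizer=str(run.get("optimizer", "generic_sa")),
        budget=int(run.get("budget", 50_000)),
        pseudocount=float(run.get("pseudocount", 1.0)),
        log_level=str(run.get("log_level", "INFO")),
        raw=raw,
    )
    # cross-reference validation
    seqs = read_fasta(cfg.sequences)
    pwms = read_pwm_counts(cfg.pwms, pseudocount=cfg.pseudocount)
    profiles = read_profiles(cfg.profiles)
    mc = cfg.model_config()
    for tf in mc.tfs:
        if tf not in pwms:
            raise ConfigError(f"TF {tf!r} has no PWM in {cfg.pwms}")
        if tf not in profiles.columns:
            raise ConfigError(f"TF {tf!r} has no profile column in {cfg.profiles}")
    for cid in seqs:
        if cid not in cfg.tss:
            raise ConfigError(f"construct {cid!r} has no TSS entry in the config")
    return cfg


def constructs_from_config(cfg: RunConfig) -> list[Construct]:
    seqs = read_fasta(cfg.sequences)
    return [
        Construct(construct_id=cid, sequence=seq, tss_position=cfg.tss[cid])
        for cid, seq in sorted(seqs.items())
    ]


def provenance(cfg: RunConfig, seed: int) -> dict:
    """Reproducibility record written alongside every CLI run."""
    from . import __version__

    digest = hashlib.sha256(
        yaml.safe_dump(cfg.raw, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {"config_sha256": digest, "seed": seed, "version": __version__}
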