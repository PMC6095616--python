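"""End-to-end pipeline orchestration and run configuration.

``run_pipeline`` chains standardize -> all-pairs LAC -> top-pair
selection -> H matrix -> Dynamic Component extraction -> optional
varimax -> per-component gamma/lfdr association, writing TSV outputs
and a manifest (config, seed, input checksum) so a run can be replayed
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from dyncorr import io as dio
from dyncorr import lac as dlac
from dyncorr import core as dcore
from dyncorr import association as dassoc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their standard defaults.

    Defaults: absolute-form LAC; top 2.5% of pairs (capped at 10^6)
    for the H matrix; 10 components, varimax-rotated; a 20% candidate
    pool and lfdr cutoff 0.01 for per-component association.
    """

    form: str = "absolute"
    top_frac: float = 0.025
    max_pairs: int = 1_000_000
    k: int = 10
    rotate: bool = True
    pool_frac: float = 0.20
    fdr: float = 0.01
    enrich_p: float = 0.001
    enrich_fc: float = 4.0
    min_set_size: int = 100
    max_set_size: int = 1000
    min_connections: int = 50
    max_zero_frac: float = 1.0
    log1p: bool = False
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(float(raw))
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig, input_path: str | Path,
                 out_dir: str | Path) -> dict:
    """Run the full analysis on an expression matrix file.

    Writes, under `out_dir`: standardized ids + component scores
    (``dc_scores.tsv``), eigenvalues (``eigenvalues.tsv``), selected
    top pairs (``top_pairs.tsv``), per-component association tables
    (``dc<k>_pairs.tsv``), and a ``manifest.json``.  Returns a dict of
    in-memory results for programmatic use.
    """
    t0 = time.time()
    input_path = Path(input_path)
    if not input_path.exists():
        raise FileNotFoundError(str(input_path))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    X = dio.read_expression(input_path)
    logger.info("loaded %d genes x %d samples", X.n_genes, X.n_samples)
    X = dio.prepare(X, max_zero_frac=config.max_zero_frac, log1p=config.log1p)
    logger.info("after preprocessing: %d genes", X.n_genes)

    table = dlac.lac_matrix(X, form=config.form)
    top = dlac.select_top_pairs(table, top_frac=config.top_frac,
                                max_pairs=config.max_pairs)
    logger.info("selected %d of %d pairs for H", top.shape[0], table.n_pairs)

    H = dcore.build_h(X, top)
    k = min(config.k, X.n_samples)
    dcs = dcore.extract_dcs(H, K=k)
    if config.rotate and k >= 2:
        dcs = dcore.varimax_rotate(dcs, H)

    scores = pd.DataFrame(
        dcs.scores, index=list(X.sample_ids),
        columns=[f"DC{i+1}" for i in range(k)],
    )
    scores.index.name = "sample_id"
    scores.to_csv(out_dir / "dc_scores.tsv", sep="\t")
    pd.DataFrame({
        "component": np.arange(1, dcs.all_eigenvalues.size + 1),
        "eigenvalue": dcs.all_eigenvalues,
    }).to_csv(out_dir / "eigenvalues.tsv", sep="\t", index=False)

    pd.DataFrame({
        "gene_id_1": [X.gene_ids[i] for i in top[:, 0]],
        "gene_id_2": [X.gene_ids[j] for j in top[:, 1]],
    }).to_csv(out_dir / "top_pairs.tsv", sep="\t", index=False)

    pool = dassoc.candidate_pool(table, pool_frac=config.pool_frac)
    associations = {}
    for ci in range(k):
        g = dassoc.gamma_stats(X, pool, dcs.scores[:, ci], dc_index=ci,
                               pool_frac=config.pool_frac)
        try:
            fit = dassoc.fit_lfdr(g, threshold=config.fdr)
        except ValueError as exc:
            logger.warning("lfdr fit failed for DC%d: %s", ci + 1, exc)
            continue
        pairs, signs = dassoc.select_pairs_for_dc(fit, fdr_cut=config.fdr)
        keep = fit.lfdr <= config.fdr
        df = pd.DataFrame({
            "gene_id_1": [X.gene_ids[i] for i in pairs[:, 0]],
            "gene_id_2": [X.gene_ids[j] for j in pairs[:, 1]],
            "gamma": fit.gamma[keep],
            "lfdr": fit.lfdr[keep],
            "sign": signs,
        })
        df.to_csv(out_dir / f"dc{ci+1}_pairs.tsv", sep="\t", index=False)
        associations[ci] = (fit, pairs, signs)
        logger.info("DC%d: %d pairs at lfdr <= %g (pi0=%.3f)",
                    ci + 1, pairs.shape[0], config.fdr, fit.pi0)

    manifest = {
        "config": asdict(config),
        "input": str(input_path),
        "input_sha256": _checksum(input_path),
        "n_genes": X.n_genes,
        "n_samples": X.n_samples,
        "n_pairs_total": int(table.n_pairs),
        "n_pairs_selected": int(top.shape[0]),
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "matrix": X,
        "pair_table": table,
        "top_pairs": top,
        "h": H,
        "dcs": dcs,
        "associations": associations,
        "manifest": manifest,
    }
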