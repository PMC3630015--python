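"""End-to-end pipeline: data -> fit -> similarity -> {network, CIM, circle}.

:class:`RunConfig` mirrors the CLI flags; :func:`run_pipeline` executes the
stages in order, writes every artifact into the output directory and logs
parameters and versions.  Identical config and seed give identical numeric
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cca import fit_cca, fit_rcca
from .cim import cluster_similarity, render_cim
from .circleplot import circle_coords, render_circle
from .io import fit_to_json, read_paired, write_dataset, write_similarity
from .network import build_network, connected_components, export_network
from .pls import CCA_METHODS, fit_pls, fit_spls
from .similarity import similarity_from_fit, variable_coordinates
from .simdata import SimulationDesign, simulate_pair

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("paircorr")

METHODS = {"cca", "rcca", "pls-reg", "pls-can", "spls-reg", "spls-can"}


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    method: str = "pls-can"
    n_dim: int = 3
    out_dir: str = "paircorr_out"
    x_path: str | None = None
    y_path: str | None = None
    simulate: bool = False
    seed: int = 42
    keep_x: list[int] | None = None
    keep_y: list[int] | None = None
    lambda1: float | None = None
    lambda2: float | None = None
    similarity_d: int | None = None
    thresholds: list[float] = field(default_factory=lambda: [0.5])
    cim_metric: str = "euclidean"
    cim_linkage: str = "ward"
    circle_dims: tuple[int, int] = (1, 2)
    force: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {sorted(METHODS)}")
        is_cca = self.method in CCA_METHODS
        is_sparse = self.method.startswith("spls")
        if (self.lambda1 is not None or self.lambda2 is not None) and not is_cca:
            raise ValueError("lambda parameters apply only to the CCA family")
        if self.method == "rcca" and (self.lambda1 is None or self.lambda2 is None):
            raise ValueError("rcca requires lambda1 and lambda2")
        if (self.keep_x is not None or self.keep_y is not None) and not is_sparse:
            raise ValueError("keepX/keepY apply only to the sparse PLS family")
        if not self.simulate:
            for path, what in ((self.x_path, "X"), (self.y_path, "Y")):
                if path is None:
                    raise ValueError(f"{what} input path required unless simulate=true")
                if not Path(path).exists():
                    raise ValueError(f"{what} input path does not exist: {path}")
        if self.n_dim < 1:
            raise ValueError("n_dim must be positive")
        d = self.similarity_d
        if d is not None and not 1 <= d <= self.n_dim:
            raise ValueError("similarity_d must lie in [1, n_dim]")
        for t in self.thresholds:
            if not 0 <= t <= 1:
                raise ValueError("thresholds must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "circle_dims" in raw:
            raw["circle_dims"] = tuple(raw["circle_dims"])
        return cls(**raw)


def _fit(config: RunConfig, data):
    m = config.method
    if m == "cca":
        return fit_cca(data, config.n_dim)
    if m == "rcca":
        return fit_rcca(data, config.n_dim, config.lambda1, config.lambda2)
    if m.startswith("spls"):
        return fit_spls(data, config.n_dim, m.split("-")[1], config.keep_x, config.keep_y)
    return fit_pls(data, config.n_dim, m.split("-")[1])


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Artifacts: ``X.tsv``/``Y.tsv`` (when simulating), ``fit.json``,
    ``M.tsv``, ``net_<threshold>.graphml``, ``cim.png``, ``circle.png``
    and ``run.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        logger.info("paircorr %s; method=%s n_dim=%d seed=%d", __version__,
                    config.method, config.n_dim, config.seed)
        stage = "input"
        try:
            if config.simulate:
                data = simulate_pair(SimulationDesign(), seed=config.seed)
                write_dataset(data, out / "X.tsv", out / "Y.tsv")
            else:
                data = read_paired(config.x_path, config.y_path)
            logger.info("data: n=%d p=%d q=%d", data.n, data.p, data.q)

            stage = "fit"
            fit = _fit(config, data)
            _check_overwrite(out / "fit.json", config.force)
            fit_to_json(fit, out / "fit.json")
            logger.info("fit rho: %s", [round(r, 4) for r in fit.rho])

            stage = "similarity"
            d = config.similarity_d or config.n_dim
            sim = similarity_from_fit(fit, data, d)
            write_similarity(sim, out / "M.tsv")

            stage = "network"
            for t in config.thresholds:
                net = build_network(sim, t)
                export_network(net, out / f"net_{t:g}.graphml")
                comps = connected_components(net)
                logger.info(
                    "threshold %.3g: %d nodes, %d edges, %d components",
                    t, net.n_nodes, net.n_edges, len(comps),
                )

            stage = "cim"
            cim = cluster_similarity(sim, config.cim_metric, config.cim_linkage)
            render_cim(cim, out / "cim.png")
            (out / "cim.json").write_text(json.dumps({
                "row_order": cim.row_ids,
                "col_order": cim.col_ids,
                "row_linkage": cim.row_linkage.tolist(),
                "col_linkage": cim.col_linkage.tolist(),
            }))

            stage = "circle"
            cx, cy = variable_coordinates(fit, data, d)
            if max(config.circle_dims) <= d and d >= 2:
                table = circle_coords(cx, cy, config.circle_dims)
                render_circle(table, out / "circle.png", dim_pair=config.circle_dims)
        except Exception as err:
            logger.error("stage %s failed: %s", stage, err)
            raise RuntimeError(f"[{stage}] {err}") from err
        logger.info("done: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True/--force to overwrite")
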