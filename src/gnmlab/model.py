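"""Model/Results interface over the generative-model machinery.

:class:`GenerativeNetworkModel` bundles the data (a target binary network
and its spatial embedding) with a wiring-rule family; ``fit()`` runs the
Voronoi-tessellation search and returns a :class:`GNMFitResults` carrying
the parameter estimates, the full evaluation table, goodness-of-fit
diagnostics against the target, a ``summary()`` table, and ``simulate()``
for drawing further networks at the fitted parameters.

Example
-------
>>> emb = make_embedding(80, "shell", 100.0, seed=0)
>>> target = plant_target(emb, m=240, decay=0.1, seed=0).network
>>> model = GenerativeNetworkModel(target, emb)          # spatial rule
>>> res = model.fit(budget="small", seed=1)
>>> print(res.summary())                                 # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analyses import probability_vs_distance
from .embedding import SpatialEmbedding, make_embedding  # noqa: F401 (docstring example)
from .engine import GNMParams, ModelSpec, grow_network
from .measures import (DEFAULT_BIN_EDGES, distance_binned_recovery,
                       fit_result)
from .network import BinaryNetwork
from .optimize import (Budget, OptimizationResult, REFERENCE_BUDGET, SMALL_BUDGET,
                       SearchSpace, optimize, replace_params)
from .synth import plant_target  # noqa: F401 (docstring example)

__all__ = ["GenerativeNetworkModel", "GNMFitResults"]

_BUDGETS = {"reference": REFERENCE_BUDGET, "small": SMALL_BUDGET,
            "tiny": Budget(init=60, rounds=2, per_round=20,
                           beta_schedule=(1.0, 2.0))}


class GenerativeNetworkModel:
    """A generative wiring-rule model of one target network.

    Parameters
    ----------
    target
        The binary network the model should reproduce (defines n and m).
        A list of networks is treated as an ensemble: the objective is
        the mean max(KS) over its members.
    embedding
        Node coordinates and wiring costs shared by target and model.
    feature_source
        ``None``/``"spatial"``, ``"matching"``, or an (n, n) similarity
        matrix in [0, 1].
    form, decay
        Wiring-rule form (``additive``/``multiplicative``) and distance
        kernel (``exponential``/``powerlaw``).
    """

    def __init__(self, target, embedding: SpatialEmbedding,
                 feature_source=None, form: str = "additive",
                 decay: str = "exponential", label: str | None = None):
        self.targets = target if isinstance(target, list) else [target]
        for t in self.targets:
            if t.n != embedding.n:
                raise ValueError("target and embedding disagree on node count")
        self.embedding = embedding
        params = GNMParams(form=form, decay=decay)
        self.spec_template = ModelSpec(params=params,
                                       feature_source=feature_source,
                                       label=label or "")
        self.label = self.spec_template.label

    @classmethod
    def from_files(cls, network_path, coords_path, n_nodes: int | None = None,
                   **kwargs) -> "GenerativeNetworkModel":
        from .io import read_coords, read_network
        emb = read_coords(coords_path)
        net = read_network(network_path, n_nodes or emb.n)
        return cls(net, emb, **kwargs)

    @property
    def target(self) -> BinaryNetwork:
        return self.targets[0]

    @property
    def m(self) -> int:
        return self.targets[0].m

    def fit(self, budget="small", seed: int | None = None,
            space: SearchSpace | None = None, n_realizations: int = 1,
            n_final: int = 20, grow_method: str = "auto") -> "GNMFitResults":
        """Fit eta/gamma/alpha by minimising max(KS).

        ``budget`` is ``"reference"`` (2000 + 4x2000), ``"small"``
        (500 + 4x250), ``"tiny"`` (smoke tests), or a
        :class:`~gnmlab.optimize.Budget`. ``n_final`` networks are regrown
        at the optimum for the goodness-of-fit diagnostics in
        ``summary()``.
        """
        if isinstance(budget, str):
            budget = _BUDGETS[budget]
        opt = optimize(self.spec_template,
                       self.targets if len(self.targets) > 1 else self.target,
                       self.embedding, space=space, budget=budget, seed=seed,
                       n_realizations=n_realizations, n_final=n_final,
                       grow_method=grow_method)
        return GNMFitResults(self, opt, budget, seed)

    def simulate(self, params: GNMParams, n: int = 1,
                 seed: int | None = None, **grow_kw) -> list[BinaryNetwork]:
        """Grow ``n`` networks at the given parameters."""
        spec = replace_params(self.spec_template, params)
        ss = np.random.SeedSequence(seed)
        return [grow_network(self.embedding, spec, self.m,
                             seed=int(c.generate_state(1)[0] % (2 ** 31)),
                             trace=False, **grow_kw)[0]
                for c in ss.spawn(n)]


class GNMFitResults:
    """Fitted parameters, evaluation table and diagnostics of one model."""

    def __init__(self, model: GenerativeNetworkModel,
                 opt: OptimizationResult, budget: Budget, seed):
        self.model = model
        self.opt = opt
        self.budget = budget
        self.seed = seed
        self._diagnostics = None

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        p = self.opt.best_params
        data = {"eta": p.eta}
        if not self.model.spec_template.is_spatial:
            data["gamma"] = p.gamma
            if p.form == "additive":
                data["alpha"] = p.alpha
        return pd.Series(data, name=self.model.label)

    @property
    def best_score(self) -> float:
        return self.opt.best_score

    @property
    def evaluations(self) -> pd.DataFrame:
        return self.opt.table

    @property
    def networks(self) -> list[BinaryNetwork]:
        """Networks regrown at the fitted parameters (``n_final``)."""
        return self.opt.networks

    def best_spec(self) -> ModelSpec:
        return self.opt.best_spec()

    # -- diagnostics -------------------------------------------------------

    def diagnostics(self) -> pd.DataFrame:
        """Per-network fit measures of the regrown ensemble vs the target."""
        if self._diagnostics is None:
            rows = []
            for net in self.opt.networks:
                fr = fit_result(net, self.model.target, self.model.embedding)
                rows.append(fr.to_dict())
            self._diagnostics = pd.DataFrame(rows)
        return self._diagnostics

    def binned_recovery(self, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
        """Mean per-length-bin recovery of the regrown ensemble."""
        frames = []
        for i, net in enumerate(self.opt.networks):
            rows = distance_binned_recovery(net, self.model.target,
                                            self.model.embedding, bin_edges)
            for r in rows:
                r["network"] = i
            frames.extend(rows)
        return pd.DataFrame(frames)

    def simulate(self, n: int = 1, seed: int | None = None,
                 **grow_kw) -> list[BinaryNetwork]:
        return self.model.simulate(self.opt.best_params, n=n, seed=seed,
                                   **grow_kw)

    def mean_probability(self, seed: int | None = None) -> np.ndarray:
        """Mean per-pair connection probability of one traced run."""
        spec = self.best_spec()
        _, trace = grow_network(self.model.embedding, spec, self.model.m,
                                seed=seed, trace=True, method="stepwise")
        return trace.mean_P

    def probability_vs_distance(self, seed: int | None = None):
        return probability_vs_distance(self.mean_probability(seed),
                                       self.model.target,
                                       self.model.embedding)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        tmpl = self.model.spec_template
        lines = []
        w = 64
        lines.append("Generative Network Model Results".center(w))
        lines.append("=" * w)
        left = [
            ("Model:", self.model.label),
            ("Rule form:", tmpl.params.form),
            ("Distance decay:", tmpl.params.decay),
            ("Feature source:", tmpl.kind),
        ]
        right = [
            ("Nodes:", str(self.model.target.n)),
            ("Edges:", str(self.model.m)),
            ("Evaluations:", str(len(self.opt.table))),
            ("Objective:", "max(KS)"),
        ]
        for (ln, lv), (rn, rv) in zip(left, right):
            lines.append(f"{ln:<16}{lv:<18}{rn:<14}{rv:>14}")
        lines.append("-" * w)
        lines.append(f"{'parameter':<12}{'estimate':>12}{'search lo':>14}"
                     f"{'search hi':>14}")
        lo, hi = self.opt.space.arrays()
        for name, l, h in zip(self.opt.space.names, lo, hi):
            est = self.params.get(name, float("nan"))
            lines.append(f"{name:<12}{est:>12.4f}{l:>14.2f}{h:>14.2f}")
        lines.append("-" * w)
        lines.append(f"{'best max(KS):':<24}{self.best_score:>12.4f}")
        if self.opt.networks:
            diag = self.diagnostics()
            lines.append(f"{'ensemble mean max(KS):':<24}"
                         f"{diag['maxKS'].mean():>12.4f}"
                         f"   (n={len(self.opt.networks)})")
            lines.append(f"{'ensemble mean recovery:':<24}"
                         f"{diag['R'].mean():>12.4f}")
            lines.append(f"{'mean degree corr (rho):':<24}"
                         f"{diag['rho_degree'].mean():>12.4f}")
        lines.append("=" * w)
        lines.append("KS components of best evaluation: "
                     + "  ".join(
                         f"{k}={self.opt.table.loc[self.opt.best_index, k]:.3f}"
                         for k in ("KS_k", "KS_c", "KS_b", "KS_e")))
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Scatter of evaluated points coloured by round (1-D or 2-D)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.opt.table
        names = self.opt.space.names
        if len(names) == 1:
            ax.scatter(tab[names[0]], tab["score"], c=tab["round"], s=8,
                       cmap="viridis")
            ax.set_xlabel(names[0])
            ax.set_ylabel("max(KS)")
        else:
            sc = ax.scatter(tab[names[0]], tab[names[1]], c=tab["score"],
                            s=8, cmap="viridis")
            ax.figure.colorbar(sc, ax=ax, label="max(KS)")
            ax.set_xlabel(names[0])
            ax.set_ylabel(names[1])
        ax.set_title(f"{self.model.label}: parameter search")
        return ax

    def __repr__(self) -> str:
        ps = ", ".join(f"{k}={v:.3f}" for k, v in self.params.items())
        return (f"<GNMFitResults {self.model.label}: {ps}, "
                f"max(KS)={self.best_score:.4f}>")
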