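"""The end-to-end clustering estimator.

`DecoyClusterer` ties the pipeline together in the scikit-learn idiom:
threshold discovery, outlier filtering, metric precomputation, auxiliary
grouping, screened neighbor search, and greedy largest-cluster
extraction. The accelerated path produces clusters identical to the
brute-force all-pairs path (`brute_force=True`); the speedups are pure
pruning, not approximation.
"""

from __future__ import annotations

import time

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import filtering, grouping, neighbors, ranking, threshold as thr
from .trace import DecoySet

__all__ = ["DecoyClusterer", "cluster_decoys"]


class DecoyClusterer(ClusterMixin, BaseEstimator):
    """Cluster protein decoys by Cα RMSD and rank clusters by size.

    Parameters
    ----------
    threshold : float or None
        Neighbor cutoff d in Å. If None, discovered from the data by
        ``threshold_mode``.
    threshold_mode : {"percentile", "mostfreq"}
        Discovery method when ``threshold`` is None: sampled percentile
        of pairwise RMSDs (default) or mode-based ``d = c*f + b``.
    percentile : float or None
        Percentile x for the percentile method; None uses
        ``min(100 * n**-0.25, 10)``.
    n_rounds, sample_size : int
        Sampling schedule for threshold discovery (10 rounds of 100
        decoys) and the outlier-filter probe count (100).
    mode_coefficient : float
        c in ``d = c*f + b`` for the mode-based method.
    outlier_filter : bool
        Drop decoys farther than 2d from every sampled probe before
        clustering.
    n_references : int
        Number of reference decoys for the distance bounds.
    group_radius_factor : float
        Group radius r as a fraction of d. At the default 0.5 a whole
        group is admitted when the query shares its group (2r <= d);
        larger factors disable that shortcut but stay correct.
    use_groups, use_bounds : bool
        Ablation switches for the grouping and bound-screening
        strategies.
    brute_force : bool
        Bypass all three strategies: all-pairs RMSDs, no filtering.
        Produces identical clusters; the exactness oracle.
    best_only : bool
        Compute only the top-ranked decoy from neighbor counts (linear
        memory); ``ranking_`` then has that single round with no member
        list beyond the representative itself.
    n_top : int
        Number of ranked clusters in reports (reporting only; the full
        ranking is always computed unless ``best_only``).
    random_state : int or None
        Seed for threshold sampling and filter probes.

    Attributes
    ----------
    threshold_ : float
        Resolved cutoff d in Å.
    kept_idx_, filtered_idx_ : int arrays
        Input indices surviving / removed by the outlier filter.
    ranking_ : ClusterRanking
        Rounds of greedy extraction, in input-index terms.
    labels_ : (n_decoys,) int array
        0-based extraction round per decoy; -1 for filtered-out decoys.
    counters_ : CaseCounters
        Pruning tallies (how each pair decision was resolved).
    """

    def __init__(
        self,
        threshold: float | None = None,
        threshold_mode: str = "percentile",
        percentile: float | None = None,
        n_rounds: int = 10,
        sample_size: int = 100,
        mode_coefficient: float = 2.0 / 3.0,
        outlier_filter: bool = True,
        n_references: int = 3,
        group_radius_factor: float = 0.5,
        use_groups: bool = True,
        use_bounds: bool = True,
        brute_force: bool = False,
        best_only: bool = False,
        n_top: int = 3,
        random_state: int | None = None,
    ):
        self.threshold = threshold
        self.threshold_mode = threshold_mode
        self.percentile = percentile
        self.n_rounds = n_rounds
        self.sample_size = sample_size
        self.mode_coefficient = mode_coefficient
        self.outlier_filter = outlier_filter
        self.n_references = n_references
        self.group_radius_factor = group_radius_factor
        self.use_groups = use_groups
        self.use_bounds = use_bounds
        self.brute_force = brute_force
        self.best_only = best_only
        self.n_top = n_top
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, DecoySet):
            return X.coords, list(X.names)
        coords = np.asarray(X, dtype=float)
        if coords.ndim == 2:
            if coords.shape[1] % 3:
                raise ValueError("flat input width must be a multiple of 3")
            coords = coords.reshape(coords.shape[0], -1, 3)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"expected (n_decoys, n_residues, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("no decoys")
        if coords.shape[1] < 3:
            raise ValueError("traces need at least 3 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        return coords, [f"decoy_{i}" for i in range(coords.shape[0])]

    def fit(self, X, y=None):
        """Run the full pipeline on a DecoySet or (n_decoys, n_residues, 3) array."""
        coords, names = self._validate(X)
        self.names_ = names
        self.n_decoys_ = coords.shape[0]
        self.timings_ = {}
        ss = np.random.SeedSequence(self.random_state)
        seed_thr, seed_filt = (int(c.generate_state(1)[0] >> 1) for c in ss.spawn(2))

        # Step 1: threshold resolution
        t0 = time.perf_counter()
        self.percentile_ = None
        if self.threshold is not None:
            spec = thr.ThresholdSpec(mode="fixed", d=float(self.threshold))
        elif self.threshold_mode == "percentile":
            x = self.percentile if self.percentile is not None else thr.default_percentile(self.n_decoys_)
            d = thr.percentile_threshold(
                coords, x, n_rounds=self.n_rounds, sample_size=self.sample_size, seed=seed_thr
            )
            self.percentile_ = x
            spec = thr.ThresholdSpec(
                mode="percentile", d=d, x=x, n_rounds=self.n_rounds,
                sample_size=self.sample_size, seed=seed_thr,
            )
        elif self.threshold_mode == "mostfreq":
            d = thr.mostfreq_threshold(
                coords, c=self.mode_coefficient, n_rounds=self.n_rounds,
                sample_size=self.sample_size, seed=seed_thr,
            )
            spec = thr.ThresholdSpec(
                mode="mostfreq", d=d, n_rounds=self.n_rounds,
                sample_size=self.sample_size, c=self.mode_coefficient, seed=seed_thr,
            )
        else:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        self.threshold_ = float(spec.d)
        self.threshold_spec_ = spec
        self.timings_["threshold"] = time.perf_counter() - t0

        # Step 2: outlier filtering (a no-op under brute force: the
        # ablation disables all three strategies)
        t0 = time.perf_counter()
        if self.outlier_filter and not self.brute_force:
            kept, removed = filtering.filter_outliers(
                coords, self.threshold_, sample_size=self.sample_size, seed=seed_filt
            )
        else:
            kept, removed = np.arange(self.n_decoys_), np.empty(0, dtype=int)
        self.kept_idx_, self.filtered_idx_ = kept, removed
        sub = coords[kept]
        self.timings_["filter"] = time.perf_counter() - t0

        counters = neighbors.CaseCounters()
        if self.brute_force:
            t0 = time.perf_counter()
            nsets = neighbors.brute_force_neighbors(sub, self.threshold_, counters)
            self.timings_["neighbors"] = time.perf_counter() - t0
            self.grouping_ = None
            self.metrics_ = None
        else:
            # Step 3: precompute metrics + auxiliary grouping
            from .rmsd import precompute_metrics

            t0 = time.perf_counter()
            self.metrics_ = precompute_metrics(sub, m_refs=min(self.n_references, len(kept)))
            r = self.group_radius_factor * self.threshold_
            self.grouping_ = (
                grouping.build_groups(sub, r, self.metrics_) if self.use_groups else None
            )
            self.timings_["precompute"] = time.perf_counter() - t0

            # Step 4: neighbor search
            t0 = time.perf_counter()
            if self.best_only:
                counts = neighbors.find_neighbors(
                    sub, self.grouping_, self.metrics_, self.threshold_, counters,
                    use_bounds=self.use_bounds, use_groups=self.use_groups, count_only=True,
                )
                winner = int(np.argmax(counts))
                count = int(counts[winner])
                self.counters_ = counters
                self.best_index_ = int(kept[winner])
                self.best_count_ = count
                self.ranking_ = ranking.ClusterRanking(
                    rounds=[
                        ranking.ClusterRound(
                            1, self.best_index_, np.array([self.best_index_]), size=count
                        )
                    ]
                )
                self.labels_ = None  # member lists intentionally not materialised
                self.timings_["neighbors"] = time.perf_counter() - t0
                return self
            nsets = neighbors.find_neighbors(
                sub, self.grouping_ if self.use_groups else None, self.metrics_,
                self.threshold_, counters,
                use_bounds=self.use_bounds, use_groups=self.use_groups,
            )
            self.timings_["neighbors"] = time.perf_counter() - t0
        self.counters_ = counters

        # Step 5: greedy extraction (indices mapped back to input order)
        t0 = time.perf_counter()
        local = ranking.extract_clusters(nsets)
        self.ranking_ = ranking.ClusterRanking(
            rounds=[
                ranking.ClusterRound(r.rank, int(kept[r.representative]), kept[r.members])
                for r in local.rounds
            ]
        )
        self.labels_ = self.ranking_.labels(self.n_decoys_)
        self.n_clusters_ = len(self.ranking_)
        self.timings_["ranking"] = time.perf_counter() - t0
        return self

    # --- report helpers (used by structure_io formatters and the CLI) ---

    def decoy_name(self, i: int) -> str:
        return self.names_[i]

    def reported_rounds(self):
        return self.ranking_.top(self.n_top)


def cluster_decoys(decoys, **params) -> DecoyClusterer:
    """Fit a :class:`DecoyClusterer` on a DecoySet or coordinate array."""
    return DecoyClusterer(**params).fit(decoys)
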