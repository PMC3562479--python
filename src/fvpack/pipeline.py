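"""End-to-end orchestration: curation -> distances -> clustering ->
position importance -> binding-site geometry -> antigen statistics.

Every stage writes deterministic TSV reports; re-running with the same
configuration reproduces them byte-identically.  Cluster labels are
mapped to the packing-mode names A/B by the proline-at-L44 fraction (the
cluster richer in Pro-L44 is type A); remaining clusters are named C, D,
... by decreasing size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .antigens import (
    chi_squared_two_sample,
    classify_antigen_size,
    enrichment_table,
    quartile_threshold,
    voronoi_volume,
)
from .clustering import (
    build_distance_matrix,
    classify_by_rule,
    gini_importance,
    greedy_identity_cluster,
    select_clustering,
)
from .geometry import binding_site_width, ca_distance
from .model import (
    FvError,
    FvStructure,
    PositionId,
    extract_interface,
    resolve_H100X,
)

logger = logging.getLogger("fvpack")

_pp = PositionId.parse


@dataclass
class PipelineConfig:
    input_dir: Optional[str] = None
    metadata: Optional[str] = None
    resolution_cutoff: float = 3.0  # Å; worse (higher) resolutions dropped
    identity_threshold: float = 0.80
    min_cluster_size: int = 3
    methods: tuple[str, ...] = ("diana", "average", "complete", "ward", "single")
    k_min: int = 2
    k_max: int = 10
    ensemble_seed: int = 0
    chi2_bins: int = 8
    probe_radius: float = 1.4  # Å
    antigen_threshold: object = 505.0  # Å³, or "quartile"
    outlier_cutoff: float = 0.25
    max_missing: int = 2
    balance_kappa: bool = False

    def __post_init__(self) -> None:
        if self.resolution_cutoff <= 0 or self.probe_radius < 0:
            raise FvError("cutoffs must be positive")
        if not 0 < self.identity_threshold <= 1:
            raise FvError("identity threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)


@dataclass
class CurationReport:
    input: int
    removed_single_chain: int = 0
    removed_scfv: int = 0
    removed_redundant: int = 0
    removed_low_resolution: int = 0
    retained: int = 0

    def check(self) -> None:
        removed = (
            self.removed_single_chain
            + self.removed_scfv
            + self.removed_redundant
            + self.removed_low_resolution
        )
        if self.input - removed != self.retained:
            raise FvError("curation arithmetic violated: input - removed != retained")


def curate(
    structures: Sequence[FvStructure],
    metadata: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> tuple[list[FvStructure], CurationReport]:
    """Apply the dataset curation filters in order.

    1. drop single-chain entries; 2. drop single-chain variable fragments
    (scFv); 3. drop exact V-region sequence duplicates keeping the best
    (lowest) resolution, ties by id; 4. drop entries with resolution worse
    (higher) than the cutoff.  Optional flags ``single_chain`` / ``scfv``
    in the metadata mark the first two classes.  Kappa-set balancing via
    interface-identity clustering runs afterwards when requested.
    """
    config = config or PipelineConfig()
    meta = metadata.set_index(metadata["id"].astype(str))
    for s in structures:
        if s.id not in meta.index:
            raise FvError(f"structure {s.id}: missing metadata row")
    report = CurationReport(input=len(structures))

    def flag(sid: str, column: str) -> bool:
        if column not in meta.columns:
            return False
        v = meta.loc[sid, column]
        return bool(v) and not pd.isna(v)

    current = list(structures)
    kept = [s for s in current if not flag(s.id, "single_chain")]
    report.removed_single_chain = len(current) - len(kept)
    current = kept

    kept = [s for s in current if not flag(s.id, "scfv")]
    report.removed_scfv = len(current) - len(kept)
    current = kept

    def vregion(s: FvStructure) -> str:
        parts = []
        for c in ("L", "H"):
            seq = s.sequences.get(c)
            parts.append("" if seq is None else "".join(r for _, r in seq.items()))
        return "|".join(parts)

    def res_of(s: FvStructure) -> float:
        r = meta.loc[s.id].get("resolution", s.resolution)
        if r is None or (isinstance(r, float) and np.isnan(r)):
            return float("inf")
        return float(r)

    groups: dict[str, list[FvStructure]] = {}
    for s in current:
        groups.setdefault(vregion(s), []).append(s)
    kept = []
    for members in groups.values():
        members.sort(key=lambda s: (res_of(s), s.id))
        kept.append(members[0])
    kept.sort(key=lambda s: [x.id for x in current].index(s.id))
    report.removed_redundant = len(current) - len(kept)
    current = kept

    kept = [s for s in current if res_of(s) <= config.resolution_cutoff]
    report.removed_low_resolution = len(current) - len(kept)
    current = kept

    report.retained = len(current)
    report.check()

    if config.balance_kappa:
        kappa = [s for s in current if s.light_type == "kappa"]
        other = [s for s in current if s.light_type != "kappa"]
        sels = [extract_interface(s, config.max_missing) for s in kappa]
        clusters = greedy_identity_cluster(
            sels,
            threshold=config.identity_threshold,
            min_size=config.min_cluster_size,
            resolutions={s.id: res_of(s) for s in kappa},
        )
        centroid_ids = {cl.centroid for cl in clusters}
        current = other + [s for s in kappa if s.id in centroid_ids]
        logger.info("kappa balancing: %d clusters, %d centroids kept", len(clusters), len(centroid_ids))

    return current, report


def _mode_names(labels: np.ndarray, pro_l44: np.ndarray) -> dict[int, str]:
    """Map integer cluster labels to A/B/C... (A = Pro-L44-rich cluster)."""
    uniq = list(np.unique(labels))
    frac = {
        lab: float(np.mean(pro_l44[labels == lab])) if np.any(labels == lab) else 0.0
        for lab in uniq
    }
    sizes = {lab: int(np.sum(labels == lab)) for lab in uniq}
    a_lab = max(uniq, key=lambda lab: (frac[lab], sizes[lab]))
    rest = sorted([lab for lab in uniq if lab != a_lab], key=lambda lab: (-sizes[lab], lab))
    names = {a_lab: "A"}
    alphabet = "BCDEFGHIJKLMNOP"
    for i, lab in enumerate(rest):
        names[lab] = alphabet[i]
    return names


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    out_dir="fvpack_out",
    structures: Optional[Sequence[FvStructure]] = None,
    metadata: Optional[pd.DataFrame] = None,
    stages: Optional[Sequence[str]] = None,
) -> dict:
    """Run the analysis and write report tables.

    ``structures`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are read from ``config.input_dir``.
    ``stages`` restricts the run (curate/distances/cluster/importance/
    geometry/antigens); later stages pull in what they need.
    Returns a dict of in-memory results keyed by stage.
    """
    from .io import read_dataset, read_metadata  # lazy: gemmi

    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ("curate", "distances", "cluster", "importance", "geometry", "antigens")
    wanted = set(stages or all_stages)
    unknown = wanted - set(all_stages)
    if unknown:
        raise FvError(f"unknown stages {sorted(unknown)}")
    results: dict = {}

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.6g")

    if structures is None:
        if config.input_dir is None:
            raise FvError("no structures given and no input_dir configured")
        metadata = read_metadata(config.metadata) if config.metadata else None
        structures = read_dataset(config.input_dir, metadata)
    structures = list(structures)
    if metadata is None:
        rows = [
            {
                "id": s.id, "light_type": s.light_type, "species": s.species,
                "resolution": s.resolution, "bound": s.bound,
            }
            for s in structures
        ]
        metadata = pd.DataFrame(rows)

    logger.info("curation: %d structures in", len(structures))
    structures, report = curate(structures, metadata, config)
    results["curation"] = report
    tsv(pd.DataFrame([asdict(report)]), "curation_report.tsv")
    if wanted == {"curate"}:
        return results

    ids = [s.id for s in structures]
    by_id = {s.id: s for s in structures}

    logger.info("distance matrix over %d structures", len(ids))
    dm = build_distance_matrix(structures, max_missing=config.max_missing)
    results["distance_matrix"] = dm
    tsv(
        pd.DataFrame(dm.values, columns=dm.ids).assign(id=dm.ids)[["id"] + dm.ids],
        "distance_matrix.tsv",
    )

    # clustering + mode naming + centroid classification
    clustering = select_clustering(
        dm, methods=config.methods, k_range=range(config.k_min, config.k_max + 1)
    )
    results["clustering"] = clustering
    labels = clustering.labels
    pro_l44 = np.array(
        [by_id[i].residue(_pp("L44")) == "P" for i in dm.ids], dtype=float
    )
    names = _mode_names(labels, pro_l44)
    mode_calls = np.array([names[lab] for lab in labels])
    results["mode_calls"] = dict(zip(dm.ids, mode_calls))

    sil_rows = [
        {"method": clustering.method, "k": k, "silhouette": s}
        for k, s in sorted(clustering.silhouette_by_k.items())
    ]
    tsv(pd.DataFrame(sil_rows), "silhouette_by_k.tsv")
    (out / "dendrogram.nwk").write_text(clustering.to_newick() + "\n")

    centroids = {}
    for mode in ("A", "B"):
        members = np.nonzero(mode_calls == mode)[0]
        if len(members) == 0:
            continue
        sums = dm.values[np.ix_(members, members)].sum(axis=1)
        centroids[mode] = int(members[int(np.argmin(sums))])
    results["centroids"] = {m: dm.ids[i] for m, i in centroids.items()}

    cluster_rows = []
    for i, sid in enumerate(dm.ids):
        d_A = dm.values[i, centroids["A"]] if "A" in centroids else np.nan
        d_B = dm.values[i, centroids["B"]] if "B" in centroids else np.nan
        both = [d for d in (d_A, d_B) if not np.isnan(d)]
        cluster_rows.append(
            {
                "id": sid,
                "label": mode_calls[i],
                "d_A": d_A,
                "d_B": d_B,
                "rule_call": classify_by_rule(by_id[sid].sequences["L"]),
                "outlier": bool(both and min(both) > config.outlier_cutoff),
            }
        )
    cluster_df = pd.DataFrame(cluster_rows)
    tsv(cluster_df, "clustering.tsv")
    results["cluster_table"] = cluster_df
    if not wanted & {"importance", "geometry", "antigens"}:
        return results

    if "importance" in wanted:
        pairs = [(by_id[i].sequences["L"], by_id[i].sequences["H"]) for i in dm.ids]
        imp = gini_importance(pairs, mode_calls, seed=config.ensemble_seed)
        results["importance"] = imp
        imp_df = pd.DataFrame(
            {
                "position": imp.importances.index,
                "gini_importance": imp.importances.values,
            }
        ).sort_values("gini_importance", ascending=False)
        imp_df["rank"] = np.arange(1, len(imp_df) + 1)
        tsv(imp_df, "importance.tsv")
        top = [
            p for p in imp.ranking[:8]
        ]
        freq = imp.frequencies[imp.frequencies["position"].isin(top)]
        tsv(freq, "frequencies.tsv")

    if "geometry" in wanted:
        geo_rows = []
        for sid in dm.ids:
            s = by_id[sid]
            h100x = resolve_H100X(s.sequences["H"])
            d_pack = ca_distance(s, _pp("L36"), h100x)
            d1, d2, area = binding_site_width(s)
            geo_rows.append(
                {
                    "id": sid,
                    "label": results["mode_calls"][sid],
                    "bound": s.bound,
                    "d_L36_H100X": d_pack,
                    "d_L55_H57": d1,
                    "d_L24_H25": d2,
                    "rhomboid_area": area,
                }
            )
        geo = pd.DataFrame(geo_rows)
        results["geometry"] = geo
        tsv(geo, "geometry.tsv")

        summaries = []
        strata = [("all", geo), ("holo", geo[geo["bound"]]), ("apo", geo[~geo["bound"]])]
        for stratum, sub in strata:
            for label, grp in sub.groupby("label"):
                row = {"stratum": stratum, "label": label, "n": len(grp)}
                for col in ("d_L36_H100X", "d_L55_H57", "d_L24_H25", "rhomboid_area"):
                    row[f"{col}_mean"] = grp[col].mean()
                    row[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
                summaries.append(row)
        summary = pd.DataFrame(summaries)
        results["geometry_summary"] = summary
        tsv(summary, "geometry_summary.tsv")

        chi_rows = []
        a = geo[geo["label"] == "A"]
        b = geo[geo["label"] == "B"]
        if len(a) and len(b):
            for col in ("d_L36_H100X", "d_L55_H57", "d_L24_H25"):
                try:
                    stat, p = chi_squared_two_sample(a[col], b[col], bins=config.chi2_bins)
                except FvError as e:
                    logger.warning("chi-squared for %s skipped: %s", col, e)
                    stat, p = float("nan"), float("nan")
                chi_rows.append({"distance": col, "statistic": stat, "p": p})
        chi = pd.DataFrame(chi_rows)
        results["chi_squared"] = chi
        tsv(chi, "chi_squared.tsv")

    if "antigens" in wanted:
        ag_rows = []
        for sid in dm.ids:
            s = by_id[sid]
            if not s.bound:
                continue
            vol = voronoi_volume(s.antigen, probe=config.probe_radius)
            ag_rows.append({"id": sid, "label": results["mode_calls"][sid], "n_atoms": len(s.antigen), "volume": vol})
        ag = pd.DataFrame(ag_rows)
        if len(ag):
            if config.antigen_threshold == "quartile":
                threshold = quartile_threshold(ag["volume"])
            else:
                threshold = float(config.antigen_threshold)
            ag["threshold"] = threshold
            ag["size_class"] = [classify_antigen_size(v, threshold) for v in ag["volume"]]
            results["antigens"] = ag
            tsv(ag, "antigens.tsv")

            enr_rows = []
            small = (ag["size_class"] == "small").tolist()
            labels_bound = ag["label"].tolist()
            for mode in sorted(ag["label"].unique()):
                t = enrichment_table(labels_bound, small, mode)
                enr_rows.append({"cluster": mode, "N": t.N, "K": t.K, "n": t.n, "k": t.k, "p": t.p})
                results.setdefault("enrichment", {})[mode] = t
            tsv(pd.DataFrame(enr_rows), "enrichment.tsv")

    manifest = {
        "package": "fvpack",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_input": int(report.input),
        "n_retained": int(report.retained),
        "stages": sorted(wanted),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
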