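"""Config-driven end-to-end pipeline over synthetic cohorts.

Runs, in order: simulate (coupled structural/functional cohorts plus a
spatially autocorrelated reference map) -> connectome build -> ISV for both
modalities -> cross-modal cluster correspondence -> SA-corrected map
correlation -> group comparison, writing each stage's table plus a JSON run
manifest. All randomness flows from one root seed through named substreams,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as cio
from .connectome import ConnectivityMatrix, counts_to_probability
from .crossmodal import CrossModalCorrespondence
from .groups import RoiGrouping, permutation_group_test
from .isv import ConnectomeISV
from .parcellation import geodesic_distances
from .spatial import sa_corrected_correlation
from .synthetic import CohortSpec, make_parcellation, make_coupled_cohorts, make_sa_map

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed and a label."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(zlib.crc32(name.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of one demo pipeline run."""

    seed: int = 0
    out_dir: str = "connvar_run"
    n_subjects: int = 10
    n_rois: int = 60
    n_clusters: int = 6
    sigma_low: float = 0.2
    sigma_high: float = 0.6
    session_noise: float = 0.2
    coupling_high: float = 0.9
    min_streamlines: int = 50
    retain_fraction: float = 0.75
    n_perm: int = 1000
    n_bootstrap: int = 1000
    n_surrogates: int = 500
    sa_lengthscale: float = 30.0
    grouping: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _simulate(cfg: RunConfig):
    parc = make_parcellation(
        cfg.n_rois, cfg.n_clusters, seed=substream_seed(cfg.seed, "parcellation")
    )
    half = cfg.n_rois // 2
    sigma = np.where(np.arange(cfg.n_rois) < half, cfg.sigma_low, cfg.sigma_high)
    clusters = parc.cluster_ids
    coupling = {c: 0.0 for c in clusters}
    coupling[clusters[0]] = cfg.coupling_high
    spec = CohortSpec(
        n_subjects=cfg.n_subjects,
        parc=parc,
        sigma_profile=sigma,
        session_noise=cfg.session_noise,
        n_sessions=2,
        coupling=coupling,
        seed=substream_seed(cfg.seed, "cohorts"),
    )
    sc_counts, meg = make_coupled_cohorts(spec)
    ref_map = make_sa_map(parc, cfg.sa_lengthscale, seed=substream_seed(cfg.seed, "refmap"))
    return parc, spec, sc_counts, meg, ref_map


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full demo pipeline; returns a dict of output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}
    timings = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        parc, spec, sc_counts, meg, ref_map = _simulate(config)
        from .parcellation import save_parcellation

        save_parcellation(parc, out / "parcellation.tsv")
        cio.write_map(ref_map, parc, out / "reference_map.tsv")
        outputs["parcellation"] = str(out / "parcellation.tsv")
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] N={config.n_subjects} R={config.n_rois} "
            f"K={parc.n_clusters} ({timings[stage]:.2f}s)")

        stage = "build"
        t0 = time.perf_counter()
        sc_prob = [
            counts_to_probability(
                ConnectivityMatrix(values=c, semantics="count"),
                min_streamlines=config.min_streamlines,
            )
            for c in sc_counts
        ]
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] {len(sc_prob)} structural matrices ({timings[stage]:.2f}s)")

        stage = "isv"
        t0 = time.perf_counter()
        sc_res = ConnectomeISV(sc_prob, parc, modality="structural").fit(
            bootstrap=config.n_bootstrap, seed=substream_seed(config.seed, "boot_sc")
        )
        ses1 = [m[0] for m in meg]
        ses2 = [m[1] for m in meg]
        meg_res = ConnectomeISV(
            ses1, parc, session2=ses2, modality="functional"
        ).fit(bootstrap=config.n_bootstrap, seed=substream_seed(config.seed, "boot_meg"))
        sc_tab = sc_res.roi_table()
        sc_tab.to_csv(out / "isv_sc.tsv", sep="\t", index=False, float_format="%.12g")
        meg_res.roi_table().to_csv(
            out / "isv_meg.tsv", sep="\t", index=False, float_format="%.12g"
        )
        outputs["isv_sc"] = str(out / "isv_sc.tsv")
        outputs["isv_meg"] = str(out / "isv_meg.tsv")
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] ISV for {parc.n_rois} ROIs, both modalities "
            f"({timings[stage]:.2f}s)")

        stage = "crossmodal"
        t0 = time.perf_counter()
        cm = CrossModalCorrespondence(
            sc_res.pair_dist, meg_res.pair_dist, parc
        ).fit(n_perm=config.n_perm, seed=substream_seed(config.seed, "crossmodal"))
        cm.table(parc.cluster_ids).to_csv(
            out / "crossmodal.tsv", sep="\t", index=False, float_format="%.12g"
        )
        outputs["crossmodal"] = str(out / "crossmodal.tsv")
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] {parc.n_clusters} clusters, {config.n_perm} permutations "
            f"({timings[stage]:.2f}s)")

        stage = "sa_corr"
        t0 = time.perf_counter()
        geo = geodesic_distances(parc)
        # restrict to ROIs where both maps are defined (the streamline
        # threshold can leave ROIs unconnected, hence missing ISV)
        ok = np.isfinite(sc_res.roi_isv) & np.isfinite(ref_map)
        from .parcellation import GeodesicDistanceMatrix

        geo_ok = GeodesicDistanceMatrix(
            dist=geo.dist[np.ix_(ok, ok)], radius=geo.radius
        )
        sa = sa_corrected_correlation(
            sc_res.roi_isv[ok],
            ref_map[ok],
            geo_ok,
            n_surrogates=config.n_surrogates,
            seed=substream_seed(config.seed, "sa"),
        )
        (out / "sa_corr.json").write_text(
            json.dumps(
                {
                    "rho": sa.rho_observed,
                    "p_sa": sa.p_sa,
                    "p_naive": sa.p_naive,
                    "ci95": list(sa.ci95),
                    "n_surrogates": sa.n_surrogates,
                },
                indent=2,
            )
        )
        outputs["sa_corr"] = str(out / "sa_corr.json")
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] rho={sa.rho_observed:.3f} p_sa={sa.p_sa:.3g} "
            f"({timings[stage]:.2f}s)")

        stage = "group_test"
        t0 = time.perf_counter()
        if config.grouping:
            labels = np.array(
                [config.grouping[str(r)] for r in parc.roi_ids], dtype=object
            )
        else:
            # default grouping: first cluster = core, second = penumbra
            cl = parc.cluster_of
            ids = parc.cluster_ids
            labels = np.where(
                cl == ids[0], "core", np.where(cl == ids[1], "penumbra", "non_md")
            ).astype(object)
        grouping = RoiGrouping(labels=labels)
        gt = permutation_group_test(
            sc_res.roi_isv,
            grouping,
            comparisons=[("core", "non_md"), ("core", "penumbra"), ("penumbra", "non_md")],
            n_perm=config.n_perm,
            seed=substream_seed(config.seed, "groups"),
        )
        gt.table().to_csv(out / "group_test.tsv", sep="\t", index=False, float_format="%.12g")
        outputs["group_test"] = str(out / "group_test.tsv")
        timings[stage] = time.perf_counter() - t0
        log(f"[{stage}] {len(gt.comparisons)} comparisons ({timings[stage]:.2f}s)")
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    manifest = {
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": outputs,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    cio.write_manifest(manifest, out / "run_manifest.json")
    outputs["manifest"] = str(out / "run_manifest.json")
    return outputs


def validate_inputs(parc, cohorts: dict) -> dict:
    """Report-only consistency checks of cohort matrices against an atlas.

    ``cohorts`` maps names to either a list of matrices or a dict
    ``{"session1": [...], "session2": [...]}``. Returns a machine-readable
    ``{check_name: bool}`` report; never raises.
    """
    report = {}
    R = parc.n_rois
    for name, data in cohorts.items():
        if isinstance(data, dict):
            s1 = data.get("session1", [])
            s2 = data.get("session2", [])
            report[f"{name}:session_pairing"] = len(s1) == len(s2) and len(s1) > 0
            mats = list(s1) + list(s2)
        else:
            mats = list(data)
        shapes_ok, sym_ok = True, True
        for m in mats:
            v = m.values if hasattr(m, "values") else np.asarray(m, dtype=float)
            if v.shape != (R, R):
                shapes_ok = False
                continue
            if not np.allclose(v, v.T, atol=1e-9):
                sym_ok = False
        report[f"{name}:shape"] = shapes_ok
        report[f"{name}:symmetry"] = sym_ok
    report["all_ok"] = all(report.values())
    return report
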