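"""CLI and experiment orchestration.

Subcommands
-----------
``simulate``   forward-solve one phantom and write the S-matrix (Touchstone)
``dataset``    build a scenario dataset and save it (HDF5 + CSV manifest)
``train``      grid-search + train on a saved dataset, write a JSON report
``evaluate``   evaluate a saved dataset end to end (grid search included)
``validate``   run the solver validation suite and print a pass/fail table
``reproduce``  run the scaled-down analog of one of the published designs

Exit codes: 0 success, 2 validation failure, 3 configuration error.
"""

from __future__ import annotations

import logging
import math
import sys
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as mwio
from .analytic_oracle import CylinderProblem, cylinder_scattered_field, energy_balance
from .classify import SVMConfig, run_classification
from .em_forward import (
    ChamberModel,
    assemble_and_solve,
    compute_smatrix,
    generate_mesh,
    permittivity_on_mesh,
    ring_ports,
    solve_scattered_planewave,
    wavelength,
)
from .phantom import RigidTransform, build_phantom, tissue_permittivity
from .scenarios import (
    DehydrationScenarioConfig,
    ForwardCache,
    NoiseScenarioConfig,
    PositionScenarioConfig,
    build_dehydration_scenario,
    build_noise_scenario,
    build_position_scenario,
    default_positions,
    shuffle_split,
)

log = logging.getLogger("mwchamber")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_CONFIG = 3


# ---------------------------------------------------------------------------
# validation suite


def _check(name: str, ok: bool, detail: str) -> dict:
    return {"name": name, "ok": bool(ok), "detail": detail}


def validate_suite(fast: bool = True, *, _reciprocity_bug: float = 0.0) -> list[dict]:
    """Solver validation: oracle equivalence, reciprocity, passivity,
    mesh convergence, dehydration-table reconstruction and count checks.

    Failures are results, not exceptions.  ``fast`` trims mesh resolution for
    the expensive checks.
    """
    checks: list[dict] = []
    f = 1e9
    lam = wavelength(54.8, f)

    # dehydration table reconstruction at printed precision (the printed
    # table mixes rounding and truncation, so match within one printed ulp)
    printed = {
        "bone": ((11.28, 2.5), (12.4, 2.79), (13.5, 3.04)),
        "skin": ((37.2, 14.7), (40.9, 16.17), (44.58, 17.6)),
        "tendon": ((41.5, 12.43), (45.6, 13.66), (49.7, 14.88)),
        "muscle": ((49.8, 15.86), (54.8, 17.43), (59.73, 19.0)),
        "synovial_fluid": ((61.8, 26.3), (68.0, 29.0), (74.1, 31.6)),
    }
    worst = 0.0
    ok = True
    for tissue, cols in printed.items():
        for h, (re_p, im_p) in zip((-0.09, 0.0, 0.09), cols):
            v = tissue_permittivity(tissue, h, sf_baseline="rounded")
            for got, want in ((v.eps_real, re_p), (v.eps_imag, im_p)):
                ulp = 10.0 ** -(len(str(want).split(".")[1]) if "." in str(want) else 0)
                worst = max(worst, abs(got - want) - ulp)
                ok &= abs(got - want) <= ulp + 1e-12
    checks.append(_check("dehydration_table", ok, f"max excess {worst:.3g}"))

    # reciprocity on a 4-port toy chamber (optionally with a deliberate
    # assembly asymmetry injected by the mutation-test harness)
    ports = ring_ports(4, 6.0)
    mesh = generate_mesh(6.0, ports, lam / 9)
    sols = assemble_and_solve(
        mesh, None, ports, f, _reciprocity_bug=_reciprocity_bug
    )
    S = compute_smatrix(sols, ports, mesh, frequency=f)
    asym = float(np.max(np.abs(S.entries - S.entries.T)) / np.max(np.abs(S.entries)))
    checks.append(_check("reciprocity", asym <= 1e-6, f"asymmetry {asym:.3g}"))

    # passivity: closed lossless chamber at h = lam/20
    div = 14 if fast else 20
    ports16 = ring_ports(16, 12.0)
    mesh16 = generate_mesh(12.0, ports16, lam / div)
    lossless = build_phantom(injured=True)
    import mwchamber.em_forward as emf

    eps = permittivity_on_mesh(mesh16, lossless).real.astype(complex)
    A, pdata, dmask = emf._chamber_system(mesh16, eps, ports16, f)
    from scipy.sparse.linalg import splu

    lu = splu(A)
    solsl = []
    for p, d in zip(ports16, pdata):
        b = 2j * p.beta_cm * d["w"].astype(complex)
        b[dmask] = 0.0
        solsl.append(emf.FieldSolution(p.index, lu.solve(b), 0.0))
    Sl = compute_smatrix(solsl, ports16, mesh16, frequency=f)
    sums = energy_balance(Sl)
    ok = bool(np.all(np.abs(sums - 1.0) <= 0.02))
    checks.append(
        _check("passivity", ok, f"column power in [{sums.min():.4f}, {sums.max():.4f}]")
    )

    # Mie-oracle equivalence at h = lam/15
    prob = CylinderProblem(radius=1.0, eps_inside=45.6, eps_outside=54.8, frequency=f)
    moracle = generate_mesh(7.0, [], lam / 15, open_all=True)
    from .analytic_oracle import cylinder_eps_on_mesh

    u = solve_scattered_planewave(moracle, cylinder_eps_on_mesh(moracle, prob), 54.8 + 0j, f)
    r = np.hypot(moracle.nodes[:, 0], moracle.nodes[:, 1])
    sel = (r > 1.8) & (r < 2.8)
    u_ref = cylinder_scattered_field(prob, moracle.nodes[sel])
    rel = float(np.linalg.norm(u[sel] - u_ref) / np.linalg.norm(u_ref))
    checks.append(_check("mie_oracle", rel <= 0.02, f"relative L2 error {rel:.4f}"))

    # mesh convergence of the S-matrix
    if not fast:
        hs = [lam / 6, lam / 9, lam / 12, lam / 18]
    else:
        hs = [lam / 6, lam / 9]
    ph = build_phantom(injured=True)
    diffs = []
    for h in hs:
        m1 = generate_mesh(12.0, ports16, h)
        m2 = generate_mesh(12.0, ports16, h / 2)
        S1 = compute_smatrix(
            assemble_and_solve(m1, ph, ports16, f), ports16, m1, frequency=f
        )
        S2 = compute_smatrix(
            assemble_and_solve(m2, ph, ports16, f), ports16, m2, frequency=f
        )
        diffs.append(float(np.linalg.norm(S1.entries - S2.entries)))
    mono = all(a > b for a, b in zip(diffs, diffs[1:]))
    checks.append(
        _check("mesh_convergence", mono, "||S(h)-S(h/2)|| = "
               + ", ".join(f"{d:.4f}" for d in diffs))
    )

    # scenario count checks (cheap, no solves: use a tiny fake S-matrix)
    from .em_forward import SMatrix
    from .scenarios import _make_samples

    dummy = SMatrix(np.zeros((2, 2), dtype=complex), f, "differential")
    ds = _make_samples(dummy, (1.0, 2.0, 3.0), 5, scenario="noise", label=1,
                       split="train", master_seed=0)
    checks.append(_check("count_product", len(ds) == 15, f"3 levels x 5 seeds = {len(ds)}"))
    return checks


# ---------------------------------------------------------------------------
# experiment manifests


def run_experiment(manifest: dict, outdir: Path) -> dict:
    """End-to-end run driven by a manifest dictionary (see YAML examples).

    Returns the report dictionary; artifacts land in ``outdir``.
    """
    t_start = time.perf_counter()
    outdir.mkdir(parents=True, exist_ok=True)
    kind = manifest.get("scenario", "noise")
    solver_cfg = manifest.get("solver", {})
    n_ports = int(solver_cfg.get("n_ports", 16))
    h = solver_cfg.get("h")
    master_seed = int(manifest.get("seed", 0))

    log.info("stage: forward model (N=%d ports)", n_ports)
    model = ChamberModel(n_ports=n_ports, h=h)
    cache = ForwardCache(model)

    log.info("stage: dataset (%s)", kind)
    if kind == "noise":
        ds = build_noise_scenario(cache, NoiseScenarioConfig(), master_seed)
    elif kind == "dehydration":
        ds = build_dehydration_scenario(cache, DehydrationScenarioConfig(), master_seed)
    elif kind in ("position", "shuffled"):
        transforms = manifest.get("positions")
        if transforms is None:
            trs = default_positions()
        else:
            trs = [RigidTransform(**t) for t in transforms]
        test_position = manifest.get("test_position")
        ds = build_position_scenario(
            cache, trs, PositionScenarioConfig(), master_seed,
            test_position=test_position,
        )
        if kind == "shuffled":
            n_train = int(manifest.get("n_train", 3350))
            n_test = int(manifest.get("n_test", 1114))
            ds = shuffle_split(ds, n_train, n_test, master_seed)
        elif test_position is not None:
            # warn when the held-out placement is far from every training one
            t_held = trs[test_position]
            dmin = min(
                math.hypot(t.dx - t_held.dx, t.dz - t_held.dz)
                for i, t in enumerate(trs) if i != test_position
            )
            if dmin > 0.5:
                log.warning(
                    "held-out position is %.2f cm from the nearest training "
                    "position (> 0.5 cm); expect degraded accuracy", dmin,
                )
    else:
        raise SystemExit(EXIT_CONFIG)

    mwio.save_dataset(outdir / "dataset.h5", ds, config=manifest)
    ds.meta.assign(label=ds.labels, split=ds.split).to_csv(
        outdir / "manifest.csv", index=False
    )

    log.info("stage: classify (%d solves cached)", cache.n_solves)
    svm_cfg = SVMConfig(**manifest.get("svm", {}))
    report = run_classification(ds, svm_cfg)
    mwio.save_report(outdir / "report.json", report,
                     dataset_hash=mwio.config_hash(manifest))
    log.info("done in %.1f s:\n%s", time.perf_counter() - t_start, report.text_table())
    return report.to_dict()


# ---------------------------------------------------------------------------
# CLI


def _build_parser():
    import argparse

    ap = argparse.ArgumentParser(
        prog="mwchamber",
        description="2D microwave sensing-chamber simulator and classifier",
    )
    ap.add_argument("-v", "--verbose", action="store_true")
    ap.add_argument("-q", "--quiet", action="store_true")
    sub = ap.add_subparsers(dest="cmd", required=True)

    sim = sub.add_parser("simulate", help="forward-solve one phantom")
    sim.add_argument("--injured", action="store_true")
    sim.add_argument("--n-ports", type=int, default=16)
    sim.add_argument("--out", type=Path, default=Path("smatrix"))

    dat = sub.add_parser("dataset", help="build a scenario dataset")
    dat.add_argument("scenario", choices=["noise", "dehydration", "position", "shuffled"])
    dat.add_argument("--n-ports", type=int, default=16)
    dat.add_argument("--seed", type=int, default=0)
    dat.add_argument("--out", type=Path, default=Path("runs"))

    trn = sub.add_parser("train", help="grid-search and train on a saved dataset")
    trn.add_argument("dataset", type=Path)
    trn.add_argument("--out", type=Path, default=Path("report.json"))

    ev = sub.add_parser("evaluate", help="run a manifest end to end")
    ev.add_argument("manifest", type=Path)
    ev.add_argument("--out", type=Path, default=Path("runs"))

    val = sub.add_parser("validate", help="run the solver validation suite")
    val.add_argument("--full", action="store_true")

    rep = sub.add_parser("reproduce", help="scaled-down analog of a printed design")
    rep.add_argument("table", choices=["noise", "dehydration", "position", "shuffled"])
    rep.add_argument("--seed", type=int, default=0)
    rep.add_argument("--out", type=Path, default=Path("runs"))
    return ap


def main(argv: list[str] | None = None) -> int:
    args = _build_parser().parse_args(argv)
    level = logging.DEBUG if args.verbose else (
        logging.ERROR if args.quiet else logging.INFO
    )
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(asctime)s %(levelname)s %(message)s")

    if args.cmd == "simulate":
        model = ChamberModel(n_ports=args.n_ports)
        ph = build_phantom(injured=args.injured)
        S = model.smatrix(ph)
        mwio.write_touchstone(args.out, S)
        print(f"wrote {args.out.with_suffix(f'.s{S.n_ports}p')}")
        return EXIT_OK

    if args.cmd == "validate":
        checks = validate_suite(fast=not args.full)
        width = max(len(c["name"]) for c in checks)
        ok_all = True
        for c in checks:
            status = "PASS" if c["ok"] else "FAIL"
            ok_all &= c["ok"]
            print(f"{c['name']:<{width}}  {status}  {c['detail']}")
        return EXIT_OK if ok_all else EXIT_VALIDATION

    if args.cmd in ("dataset", "reproduce"):
        manifest = {
            "scenario": args.table if args.cmd == "reproduce" else args.scenario,
            "seed": args.seed,
            "solver": {"n_ports": getattr(args, "n_ports", 16)},
        }
        if manifest["scenario"] == "position":
            manifest["test_position"] = 2   # M2, the easy printed case
        run_experiment(manifest, args.out)
        return EXIT_OK

    if args.cmd == "train":
        ds = mwio.load_dataset(args.dataset)
        report = run_classification(ds, SVMConfig())
        mwio.save_report(args.out, report)
        print(report.text_table())
        return EXIT_OK

    if args.cmd == "evaluate":
        try:
            manifest = yaml.safe_load(args.manifest.read_text())
        except Exception as exc:
            print(f"bad manifest: {exc}", file=sys.stderr)
            return EXIT_CONFIG
        run_experiment(manifest, args.out)
        return EXIT_OK

    return EXIT_CONFIG


if __name__ == "__main__":
    raise SystemExit(main())
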