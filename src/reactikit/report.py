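"""Fixture verification and pipeline reporting.

The packaged fixtures transcribe the reference system's printed tables
(frontier orbitals and derived indices; BCP topological parameters;
per-site BDE/PDE/PA/ETE; IP per medium; condensed Fukui functions).
``verify_paper_tables`` recomputes every derivable cell from its raw
inputs and compares at the print precision, reporting known print
anomalies as *flagged* rather than failed:

* the acetic-acid Neu5Gc BCP row prints ρ = 0.2266 and G = 0.2262 where
  the virial identity confirms 0.02266 / 0.02262 (decimal-point slips);
* one gas-phase BCP row prints an H value inconsistent with its own
  G + V by slightly more than print rounding can explain;
* one gas-phase mechanism row violates the cycle closure by ~10 kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import cdft, thermo
from .aim import bcp_energetics
from .core_io import DEFAULT_MEDIA, ContractError, normalize_medium_name

log = logging.getLogger("reactikit")

#: verification tolerances per check class
TOL_TABLE2_EV = 0.002          # derived global indices, eV (print rounding)
TOL_H_BCP_AU = 1e-5            # H = G + V against the printed H column
TOL_EHB_KJ = 0.02              # E_HB = V/2 against the printed column
TOL_VIRIAL_AU = 5e-4           # ¼∇²ρ − 2G − V on printed (rounded) rows
TOL_CLOSURE_KCAL = 0.05        # IP + PDE − PA − ETE on printed rows
GAS_CYCLE_CONSTANT = DEFAULT_MEDIA["gas"].cycle_constant  # 314.53 kcal/mol


@dataclass
class Check:
    table: str
    row: str
    quantity: str
    computed: float
    printed: float
    tolerance: float
    status: str  # pass | fail | flagged
    note: str = ""


@dataclass
class VerificationReport:
    checks: list[Check] = field(default_factory=list)

    def add(self, table, row, quantity, computed, printed, tol, flag_note=None):
        ok = abs(computed - printed) <= tol
        if flag_note is not None:
            status = "flagged"
        else:
            status = "pass" if ok else "fail"
        self.checks.append(Check(table, row, quantity, float(computed),
                                 float(printed), tol, status, flag_note or ""))

    @property
    def n_pass(self):
        return sum(c.status == "pass" for c in self.checks)

    @property
    def n_fail(self):
        return sum(c.status == "fail" for c in self.checks)

    @property
    def n_flagged(self):
        return sum(c.status == "flagged" for c in self.checks)

    @property
    def passed(self) -> bool:
        return self.n_fail == 0

    def failures(self) -> list[Check]:
        return [c for c in self.checks if c.status == "fail"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.checks])


def load_fixture(name: str, fixture_dir=None) -> pd.DataFrame:
    if fixture_dir is not None:
        path = Path(fixture_dir) / name
        if not path.exists():
            raise FileNotFoundError(f"missing fixture {path}")
        return pd.read_csv(path)
    trav = resources.files("reactikit.data").joinpath(name)
    if not trav.is_file():
        raise FileNotFoundError(f"missing packaged fixture {name}")
    with trav.open("r") as fh:
        return pd.read_csv(fh)


def verify_orbital_table(fixture_dir=None,
                         report: VerificationReport | None = None) -> VerificationReport:
    """Recompute every derived global-index column from printed HOMO/LUMO."""
    report = report if report is not None else VerificationReport()
    df = load_fixture("table2_orbitals.csv", fixture_dir)
    log.info("global-index check: tolerance ±%g eV on %d rows",
             TOL_TABLE2_EV, len(df))
    for _, row in df.iterrows():
        o = cdft.OrbitalSummary(row["molecule"], row["medium"],
                                float(row["HOMO"]), float(row["LUMO"]))
        gi = cdft.global_indices(o)
        rowid = f"{row['molecule']}/{row['medium']}"
        for col, computed in (("Egap", gi.Egap), ("eta", gi.eta), ("s", gi.s),
                              ("chi", gi.chi), ("mu", gi.mu), ("omega", gi.omega)):
            report.add("orbital-indices", rowid, col, computed,
                       float(row[col]), TOL_TABLE2_EV)
    return report


def verify_bcp_table(fixture_dir=None,
                     report: VerificationReport | None = None) -> VerificationReport:
    """Recompute H = G + V, E_HB = V/2 and the virial residual per BCP row."""
    report = report if report is not None else VerificationReport()
    df = load_fixture("table1_bcp.csv", fixture_dir)
    log.info("BCP check: tolerances %g a.u. (H), %g kJ/mol (E_HB), "
             "%g a.u. (virial) on %d rows",
             TOL_H_BCP_AU, TOL_EHB_KJ, TOL_VIRIAL_AU, len(df))
    for _, row in df.iterrows():
        rowid = f"{row['molecule']}/{row['medium']}/{row['bond']}"
        flag = row["flag"] if isinstance(row["flag"], str) else ""
        d = bcp_energetics(float(row["rho"]), float(row["lap"]),
                           float(row["V"]), float(row["G"]))
        h_note = "printed H inconsistent with printed G+V beyond rounding" \
            if flag == "h_print_anomaly" else None
        report.add("bcp-energetics", rowid, "H_BCP", d["H_BCP"],
                   float(row["H_printed"]), TOL_H_BCP_AU, flag_note=h_note)
        report.add("bcp-energetics", rowid, "E_HB", d["E_HB"],
                   float(row["EHB_printed"]), TOL_EHB_KJ)
        report.add("bcp-energetics", rowid, "virial_residual",
                   d["virial_residual"], 0.0, TOL_VIRIAL_AU)
        if flag == "decimal_typo_rho_G":
            report.add("bcp-energetics", rowid, "rho_decimal_typo",
                       float(row["rho"]), float(row["rho_printed"]), 0.0,
                       flag_note="printed rho/G corrected by one decimal place "
                                 "(confirmed by the virial identity)")
    return report


def verify_mechanism_tables(fixture_dir=None,
                            report: VerificationReport | None = None) -> VerificationReport:
    """Closure identities across the mechanism and IP fixtures.

    Per (molecule, medium, site): IP + PDE = PA + ETE within 0.05 kcal/mol;
    gas rows additionally satisfy IP + PDE − BDE = 314.53 and a PDE
    re-derivation from BDE + IP + the gas reference enthalpies.
    """
    report = report if report is not None else VerificationReport()
    mech = load_fixture("table56_mechanism.csv", fixture_dir)
    ip = load_fixture("table7_ip.csv", fixture_dir)
    ip_map = {(r["molecule"], normalize_medium_name(r["medium"])): float(r["IP"])
              for _, r in ip.iterrows()}
    wide = mech.pivot_table(index=["molecule", "medium", "site"],
                            columns="quantity", values="value").reset_index()
    flags = {(r["molecule"], r["medium"], r["site"]): r["flag"]
             for _, r in mech.iterrows() if isinstance(r["flag"], str) and r["flag"]}
    log.info("mechanism closure check: tolerance %g kcal/mol on %d site rows",
             TOL_CLOSURE_KCAL, len(wide))
    gas_medium = DEFAULT_MEDIA["gas"]
    for _, row in wide.iterrows():
        mol, med, site = row["molecule"], row["medium"], row["site"]
        med_key = normalize_medium_name(med)
        rowid = f"{mol}/{med}/{site}"
        ip_val = ip_map.get((mol, med_key))
        if ip_val is None:
            raise ContractError(f"no IP fixture value for {mol}/{med}")
        flag = flags.get((mol, med, site), "")
        closure = ip_val + row["PDE"] - row["PA"] - row["ETE"]
        note = (f"printed IP+PDE and PA+ETE disagree by {closure:+.2f} "
                "kcal/mol (print anomaly)") if flag == "closure_anomaly" else None
        report.add("mechanism-closure", rowid, "IP+PDE-PA-ETE", closure, 0.0,
                   TOL_CLOSURE_KCAL, flag_note=note)
        if med_key == "gas":
            report.add("mechanism-closure", rowid, "IP+PDE-BDE",
                       ip_val + row["PDE"] - row["BDE"], GAS_CYCLE_CONSTANT,
                       TOL_CLOSURE_KCAL)
            derived = thermo.complete_cycle({"BDE": row["BDE"], "IP": ip_val},
                                            gas_medium)
            report.add("mechanism-closure", rowid, "PDE_from_BDE_IP",
                       derived["PDE"], row["PDE"], TOL_CLOSURE_KCAL)
    return report


def verify_paper_tables(fixture_dir=None) -> VerificationReport:
    """Run every fixture verification; deterministic and idempotent."""
    report = VerificationReport()
    verify_orbital_table(fixture_dir, report)
    verify_bcp_table(fixture_dir, report)
    verify_mechanism_tables(fixture_dir, report)
    log.info("verification: %d pass, %d fail, %d flagged",
             report.n_pass, report.n_fail, report.n_flagged)
    return report


# ---------------------------------------------------------------------------
# Derived reporting helpers used by the CLI and the acceptance pipeline

def global_indices_table(orbitals: pd.DataFrame) -> pd.DataFrame:
    """Derived-index table from a DataFrame with molecule/medium/HOMO/LUMO."""
    rows = []
    for _, r in orbitals.iterrows():
        gi = cdft.global_indices(cdft.OrbitalSummary(
            r["molecule"], r["medium"], float(r["HOMO"]), float(r["LUMO"])))
        rows.append({"molecule": r["molecule"], "medium": r["medium"],
                     "HOMO": r["HOMO"], "LUMO": r["LUMO"],
                     "Egap": gi.Egap, "eta": gi.eta, "s": gi.s,
                     "chi": gi.chi, "mu": gi.mu, "omega": gi.omega})
    return pd.DataFrame(rows)


def mechanism_profiles_from_fixture(fixture_dir=None) -> list[thermo.MechanismProfile]:
    """Site profiles assembled from the mechanism + IP fixtures."""
    mech = load_fixture("table56_mechanism.csv", fixture_dir)
    ip = load_fixture("table7_ip.csv", fixture_dir)
    ip_map = {(r["molecule"], normalize_medium_name(r["medium"])): float(r["IP"])
              for _, r in ip.iterrows()}
    wide = mech.pivot_table(index=["molecule", "medium", "site"],
                            columns="quantity", values="value").reset_index()
    profiles = []
    for _, row in wide.iterrows():
        med_key = normalize_medium_name(row["medium"])
        ip_val = ip_map[(row["molecule"], med_key)]
        p = thermo.MechanismProfile(
            molecule=row["molecule"], medium=med_key, site=row["site"],
            BDE=float(row["BDE"]), IP=ip_val, PDE=float(row["PDE"]),
            PA=float(row["PA"]), ETE=float(row["ETE"]),
            closure_residual=ip_val + row["PDE"] - row["PA"] - row["ETE"])
        p.preferred = thermo.preferred_mechanism(p)[0]
        profiles.append(p)
    return profiles


# ---------------------------------------------------------------------------
# Orchestration

KNOWN_STAGES = ("synth", "cdft", "fukui", "thermo", "aim", "igm")


def run_report(config: dict) -> dict[str, Path]:
    """Run the requested stages and emit CSV/cube reports plus a run log.

    ``config`` keys: ``out_dir`` (required), ``stages`` (list, may be
    empty), ``seed`` (int, default 0), ``fixture_dir`` (optional override),
    ``spacing``/``padding`` for the grid stage. When the ``synth`` stage
    runs first, later stages consume its outputs; otherwise they run on the
    packaged fixtures. Unknown stage names raise :class:`ContractError`.
    """
    from . import __version__, igm, synthetic
    from .cdft import FukuiVector, condensed_fukui, rank_fukui
    from .core_io import DEFAULT_MEDIA, write_cube, write_xyz
    from .thermo import mechanism_profile

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    seed = int(config.get("seed", 0))
    fixture_dir = config.get("fixture_dir")
    for s in stages:
        if s not in KNOWN_STAGES:
            raise ContractError(
                f"unknown stage {s!r}; known stages: {', '.join(KNOWN_STAGES)}")

    written: dict[str, Path] = {}
    loglines = [f"reactikit {__version__}", f"seed = {seed}",
                f"stages = {stages}",
                f"tolerances: table2 ±{TOL_TABLE2_EV} eV; "
                f"H_BCP {TOL_H_BCP_AU} a.u.; E_HB {TOL_EHB_KJ} kJ/mol; "
                f"virial {TOL_VIRIAL_AU} a.u.; closure {TOL_CLOSURE_KCAL} kcal/mol"]
    synth_products: dict = {}

    for stage in stages:
        if stage == "synth":
            geom = synthetic.toy_geometry("hbonded_dimer", seed=seed)
            targets = [FukuiVector("O1", 0.12, 0.15, 0.135),
                       FukuiVector("O2", 0.03, 0.01, 0.02)]
            synth_products["triplets"] = synthetic.synth_charge_triplets(
                targets, seed=seed)
            synth_products["enthalpies"] = [synthetic.synth_enthalpy_set(
                "synthetic-mol", "O7-H", DEFAULT_MEDIA["gas"],
                BDE=104.0, IP=134.0, PA=49.8, seed=seed)]
            synth_products["bcp"] = synthetic.synth_bcp_records(
                ["weak", "medium", "strong"], seed=seed)
            synth_products["geometry"] = geom
            path = out_dir / "synthetic_geometry.xyz"
            write_xyz(geom, path)
            written["synth"] = path
            loglines.append(f"synth: dimer {geom.name}, "
                            f"{len(synth_products['triplets'])} triplets, "
                            f"{len(synth_products['bcp'])} BCP records")
        elif stage == "cdft":
            df = global_indices_table(
                load_fixture("table2_orbitals.csv", fixture_dir))
            path = out_dir / "global_indices.csv"
            df.to_csv(path, index=False)
            written["cdft"] = path
            loglines.append(f"cdft: {len(df)} molecule x medium rows")
        elif stage == "fukui":
            if "triplets" in synth_products:
                vecs = [condensed_fukui(t) for t in synth_products["triplets"]]
                rows = [{"atom": v.atom, "f_minus": v.f_minus,
                         "f_plus": v.f_plus, "f_zero": v.f_zero}
                        for v in vecs]
                df = pd.DataFrame(rows)
            else:
                fk = load_fixture("table34_fukui.csv", fixture_dir)
                rows = []
                for (mol, med, idx), grp in fk.groupby(
                        ["molecule", "medium", "index"]):
                    vecs = [FukuiVector(a, v, v, v) for a, v in
                            zip(grp["atom"], grp["value"])]
                    for rank, ra in enumerate(rank_fukui(vecs, "f-"), start=1):
                        rows.append({"molecule": mol, "medium": med,
                                     "index": idx, "rank": rank,
                                     "atom": ra.atom, "value": ra.value,
                                     "tied": ra.tied})
                df = pd.DataFrame(rows)
            path = out_dir / "fukui.csv"
            df.to_csv(path, index=False)
            written["fukui"] = path
            loglines.append(f"fukui: {len(df)} rows")
        elif stage == "thermo":
            if "enthalpies" in synth_products:
                profiles = [mechanism_profile(s, DEFAULT_MEDIA["gas"])
                            for s in synth_products["enthalpies"]]
            else:
                profiles = mechanism_profiles_from_fixture(fixture_dir)
            rows = [{"molecule": p.molecule, "medium": p.medium, "site": p.site,
                     **p.as_dict(), "closure_residual": p.closure_residual,
                     "preferred": "/".join(p.preferred)} for p in profiles]
            df = pd.DataFrame(rows)
            path = out_dir / "mechanism_profiles.csv"
            df.to_csv(path, index=False)
            written["thermo"] = path
            loglines.append(f"thermo: {len(df)} site profiles")
        elif stage == "aim":
            if "bcp" in synth_products:
                records = synth_products["bcp"]
            else:
                from .aim import evaluate_bcp
                t1 = load_fixture("table1_bcp.csv", fixture_dir)
                records = [evaluate_bcp(r["bond"], float(r["rho"]),
                                        float(r["lap"]), float(r["V"]),
                                        float(r["G"]))
                           for _, r in t1.iterrows()]
            rows = [{"bond": r.bond, "rho": r.rho, "lap": r.lap, "V": r.V,
                     "G": r.G, "H_BCP": r.H_BCP, "E_HB_kJmol": r.E_HB,
                     "virial_residual": r.virial_residual,
                     "class": r.hb_class,
                     "in_qualitative_range": r.in_qualitative_range}
                    for r in records]
            df = pd.DataFrame(rows)
            path = out_dir / "bcp_classification.csv"
            df.to_csv(path, index=False)
            written["aim"] = path
            loglines.append(f"aim: {len(df)} BCP records")
        elif stage == "igm":
            geom = synth_products.get("geometry")
            if geom is None:
                from . import synthetic as _synthetic
                geom = _synthetic.toy_geometry("hbonded_dimer", seed=seed)
            model = igm.load_density_model(config.get("density_model"))
            result = igm.igm_grid_analysis(
                geom, model,
                spacing=float(config.get("spacing", igm.DEFAULT_GRID_SPACING)),
                padding=float(config.get("padding", igm.DEFAULT_GRID_PADDING)))
            for key in ("rho", "rdg", "delta_g", "sign_lambda2_rho"):
                if key in result:
                    path = out_dir / f"{key}.cube"
                    write_cube(result[key], geom, path)
                    written[f"igm:{key}"] = path
            path = out_dir / "scatter.csv"
            result["scatter"].to_csv(path, index=False)
            written["igm:scatter"] = path
            loglines.append(
                f"igm: grid dims {result['grid'].dims}, "
                f"{len(result['scatter'])} scatter points")

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(loglines) + "\n")
    written["log"] = log_path
    return written
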