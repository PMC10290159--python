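"""Transcription-translation network of the extended core clock.

The network couples the core-clock genes (ARNTL, CLOCK, PER, CRY, NR1D,
ROR, PAR/DBP, NFIL3, PPARA — PER/CRY/NR1D lumped over their paralogs) to
the four irinotecan-metabolism mRNAs (CES2, ABCB, ABCC, UGT1A1). Topology
is declarative: a config lists mRNA species with Hill-type transcriptional
regulation and protein species (translation products and nuclear
complexes); :func:`build_network` validates the config and compiles it
into a fast ODE right-hand side.

Regulatory logic of the default wild-type topology:

* ARNTL and CLOCK transcription — activated by nuclear ROR, inhibited by
  nuclear NR1D (REV-ERB) at RORE elements (inhibition constants ``k_i5``
  and ``k_i6``).
* E-box genes (PER, CRY, NR1D, ROR, PAR, PPARA) — activated by the
  nuclear CLOCK:ARNTL complex, inhibited by the nuclear PER:CRY complex
  (modelled as blocking of DNA-bound CLOCK:ARNTL).
* NFIL3 inhibits PER; NFIL3 inhibits NR1D at the D-box, which makes
  NFIL3 an *indirect* activator of CES2 (via relief of NR1D repression) —
  there is no direct NFIL3 -> CES2 edge.
* CES2 — activated by PAR, inhibited by NR1D and by PPARA.
* ABCB / ABCC — D-box regulation where the activator PAR and the
  repressor NFIL3 compete for the same binding sites (competitive form).
* UGT1A1 — activated by PAR, inhibited by NR1D.
* TOP1 is not part of the transcription network (constant protein in the
  PK-PD layer).

Light/Zeitgeber forcing multiplies the maximal transcription rate of the
target gene (PER for light, NR1D for pharmacological cues).
"""

from __future__ import annotations

import copy

import numpy as np
import yaml

from .params import ParameterSet
from .zeitgeber import ZeitgeberSchedule, effective_transcription_rate  # noqa: F401

__all__ = [
    "TopologyError",
    "ClockParameters",
    "ODESystem",
    "build_network",
    "default_topology",
    "load_topology",
]

CLOCK_PERIOD_H = 24.0  # Zeitgeber day length used for circadian modulation terms


class TopologyError(ValueError):
    """Raised for invalid network topology configurations."""


class ClockParameters(ParameterSet):
    """Rate constants of the transcription-translation network."""


# ---------------------------------------------------------------------------
# default wild-type topology
# ---------------------------------------------------------------------------

def _m(name, vmax, regulation, deg, zeitgeber=False, basal=0.15):
    return {"name": name, "vmax": [f"V_{name}", vmax],
            "regulation": regulation, "degradation": [f"dm_{name}", deg],
            "basal": [f"b_{name}", basal],
            "zeitgeber_target": zeitgeber}


def _act(reg, kname, k, nname, n):
    return {"type": "activate", "regulator": reg, "k": [kname, k], "n": [nname, n]}


def _inh(reg, kname, k, nname, n):
    return {"type": "inhibit", "regulator": reg, "k": [kname, k], "n": [nname, n]}


def _cmp(act, inh, kaname, ka, kiname, ki, nname, n):
    return {"type": "compete", "activator": act, "inhibitor": inh,
            "ka": [kaname, ka], "ki": [kiname, ki], "n": [nname, n]}


def _tr(name, mrna, ktl, deg, degname=None):
    return {"name": name, "kind": "translate", "mrna": mrna,
            "ktl": [f"ktl_{mrna}", ktl],
            "deg": [degname or f"dp_{mrna}", deg]}


def _cx(name, partners, kass, deg, degname):
    return {"name": name, "kind": "complex", "partners": list(partners),
            "kass": [f"kass_{name}", kass], "deg": [degname, deg]}


def _imp(name, source, kimp, deg, degname):
    return {"name": name, "kind": "import", "source": source,
            "kimp": [f"kimp_{name}", kimp], "deg": [degname, deg]}


# Default wild-type rate constants (per hour; concentrations in arbitrary
# CPM-like units). The set yields a self-sustained oscillator whose
# free-running period is fixed by time-rescaling to 23.8 h (slightly short
# of 24 h, as typical for human peripheral clocks) with relative mRNA
# amplitudes well above the 5% floor for every gene.
_DEFAULT_RATES = {
    "V_ARNTL": 1.39044, "dm_ARNTL": 0.243105, "ka_ARNTL_ROR": 2.5,
    "n_ARNTL_ROR": 2, "k_i5": 3.23948, "n_i5": 2, "b_ARNTL": 0.202617,
    "V_CLOCK": 2.42378, "dm_CLOCK": 0.243105, "ka_CLOCK_ROR": 2.5,
    "n_CLOCK_ROR": 2, "k_i6": 0.824375, "n_i6": 2, "b_CLOCK": 0.202617,
    "V_PER": 2.93743, "dm_PER": 0.16295, "ka_PER_CB": 2.70856,
    "n_PER_CB": 2, "ki_PER_PC": 0.517567, "n_PER_PC": 6,
    "ki_PER_NFIL3": 6, "n_PER_NFIL3": 2, "b_PER": 0.202617,
    "V_CRY": 1.78522, "dm_CRY": 0.16295, "ka_CRY_CB": 2.70856,
    "n_CRY_CB": 2, "ki_CRY_PC": 0.517567, "n_CRY_PC": 6,
    "ki_CRY_NR1D": 3, "n_CRY_NR1D": 2, "b_CRY": 0.202617,
    "V_NR1D": 2.13932, "dm_NR1D": 0.291726, "ka_NR1D_CB": 3,
    "n_NR1D_CB": 2, "ki_NR1D_PC": 0.517567, "n_NR1D_PC": 6,
    "ki_NR1D_NFIL3": 5, "n_NR1D_NFIL3": 2, "b_NR1D": 0.202617,
    "V_ROR": 1.55587, "dm_ROR": 0.243105, "ka_ROR_CB": 3, "n_ROR_CB": 2,
    "ki_ROR_PC": 0.517567, "n_ROR_PC": 6, "b_ROR": 0.202617,
    "V_PAR": 1.75036, "dm_PAR": 0.243105, "ka_PAR_CB": 3, "n_PAR_CB": 2,
    "ki_PAR_PC": 0.517567, "n_PAR_PC": 6, "b_PAR": 0.202617,
    "V_NFIL3": 1.36139, "dm_NFIL3": 0.243105, "ka_NFIL3_ROR": 2.5,
    "n_NFIL3_ROR": 2, "ki_NFIL3_NR1D": 2, "n_NFIL3_NR1D": 2,
    "b_NFIL3": 0.202617,
    "V_PPARA": 1.1669, "dm_PPARA": 0.194484, "ka_PPARA_CB": 3,
    "n_PPARA_CB": 2, "ki_PPARA_PC": 2.5, "n_PPARA_PC": 2,
    "b_PPARA": 0.202617,
    "V_CES2": 1.55587, "dm_CES2": 0.194484, "ka_CES2_PAR": 2,
    "n_CES2_PAR": 2, "ki_CES2_NR1D": 2.5, "n_CES2_NR1D": 2,
    "ki_CES2_PPARA": 3, "n_CES2_PPARA": 2, "b_CES2": 0.202617,
    "V_ABCB": 1.36139, "dm_ABCB": 0.194484, "ka_ABCB_PAR": 2,
    "ki_ABCB_NFIL3": 2, "n_ABCB": 2, "b_ABCB": 0.202617,
    "V_ABCC": 1.36139, "dm_ABCC": 0.194484, "ka_ABCC_PAR": 2.5,
    "ki_ABCC_NFIL3": 1.6, "n_ABCC": 2, "b_ABCC": 0.202617,
    "V_UGT1A1": 0.97242, "dm_UGT1A1": 0.194484, "ka_UGT1A1_PAR": 2,
    "n_UGT1A1_PAR": 2, "ki_UGT1A1_NR1D": 2.5, "n_UGT1A1_NR1D": 2,
    "b_UGT1A1": 0.202617,
    "ktl_ARNTL": 0.583452, "dp_ARNTL": 0.243105,
    "ktl_CLOCK": 0.583452, "dp_CLOCK": 0.243105,
    "kass_CB_c": 1.11771, "dp_CBc": 0.150904,
    "kimp_CB": 0.150317, "d_x2": 0.198069,
    "ktl_PER": 0.431936, "dp_PER": 0.16295,
    "ktl_CRY": 0.431936, "dp_CRY": 0.16295,
    "kass_PC_c": 0.228682, "dp_PCc": 0.16295,
    "kimp_PC": 0.190848, "d_x1": 0.16295,
    "ktl_NR1D": 0.583452, "d_x5": 0.194484,
    "ktl_ROR": 0.583452, "d_x6": 0.194484,
    "ktl_PAR": 0.583452, "dp_PAR": 0.194484,
    "ktl_NFIL3": 0.583452, "dp_NFIL3": 0.194484,
    "ktl_PPARA": 0.583452, "dp_PPARA": 0.194484,
}


def _override_rates(node, rates):
    """Replace the default value of every [name, value] pair found in
    ``rates``, recursively, in place."""
    if isinstance(node, list):
        if (len(node) == 2 and isinstance(node[0], str)
                and isinstance(node[1], (int, float))):
            if node[0] in rates:
                node[1] = float(rates[node[0]])
            return
        for item in node:
            _override_rates(item, rates)
    elif isinstance(node, dict):
        for v in node.values():
            _override_rates(v, rates)


def default_topology() -> dict:
    """Wild-type topology with the package's default rate constants.

    Rates are per hour, concentrations in arbitrary CPM-like units. The
    defaults are chosen to give a self-sustained oscillator with a
    free-running period of 23.8 h (human peripheral-clock range) and
    relative mRNA amplitudes well above the 5% floor.
    """
    mrnas = [
        _m("ARNTL", 1.6, [
            _act("ROR_n", "ka_ARNTL_ROR", 2.5, "n_ARNTL_ROR", 2.0),
            _inh("NR1D_n", "k_i5", 1.8, "n_i5", 2.0),
        ], 0.25),
        _m("CLOCK", 1.2, [
            _act("ROR_n", "ka_CLOCK_ROR", 2.5, "n_CLOCK_ROR", 2.0),
            _inh("NR1D_n", "k_i6", 2.2, "n_i6", 2.0),
        ], 0.25),
        _m("PER", 2.4, [
            _act("CB", "ka_PER_CB", 3.0, "n_PER_CB", 2.0),
            _inh("PC", "ki_PER_PC", 2.2, "n_PER_PC", 4.0),
            _inh("NFIL3_n", "ki_PER_NFIL3", 6.0, "n_PER_NFIL3", 2.0),
        ], 0.3, zeitgeber=True),
        _m("CRY", 2.0, [
            _act("CB", "ka_CRY_CB", 3.0, "n_CRY_CB", 2.0),
            _inh("PC", "ki_CRY_PC", 2.2, "n_CRY_PC", 4.0),
            _inh("NR1D_n", "ki_CRY_NR1D", 3.0, "n_CRY_NR1D", 2.0),
        ], 0.25),
        _m("NR1D", 2.2, [
            _act("CB", "ka_NR1D_CB", 3.0, "n_NR1D_CB", 2.0),
            _inh("PC", "ki_NR1D_PC", 2.2, "n_NR1D_PC", 4.0),
            _inh("NFIL3_n", "ki_NR1D_NFIL3", 5.0, "n_NR1D_NFIL3", 2.0),
        ], 0.3, zeitgeber=True),
        _m("ROR", 1.6, [
            _act("CB", "ka_ROR_CB", 3.0, "n_ROR_CB", 2.0),
            _inh("PC", "ki_ROR_PC", 2.2, "n_ROR_PC", 4.0),
        ], 0.25),
        _m("PAR", 1.8, [
            _act("CB", "ka_PAR_CB", 3.0, "n_PAR_CB", 2.0),
            _inh("PC", "ki_PAR_PC", 2.2, "n_PAR_PC", 4.0),
        ], 0.25),
        _m("NFIL3", 1.4, [
            _act("ROR_n", "ka_NFIL3_ROR", 2.5, "n_NFIL3_ROR", 2.0),
            _inh("NR1D_n", "ki_NFIL3_NR1D", 2.0, "n_NFIL3_NR1D", 2.0),
        ], 0.25),
        _m("PPARA", 1.2, [
            _act("CB", "ka_PPARA_CB", 3.0, "n_PPARA_CB", 2.0),
            _inh("PC", "ki_PPARA_PC", 2.5, "n_PPARA_PC", 2.0),
        ], 0.2),
        _m("CES2", 1.6, [
            _act("PAR_n", "ka_CES2_PAR", 2.0, "n_CES2_PAR", 2.0),
            _inh("NR1D_n", "ki_CES2_NR1D", 2.5, "n_CES2_NR1D", 2.0),
            _inh("PPARA_n", "ki_CES2_PPARA", 3.0, "n_CES2_PPARA", 2.0),
        ], 0.2),
        _m("ABCB", 1.4, [
            _cmp("PAR_n", "NFIL3_n", "ka_ABCB_PAR", 2.0,
                 "ki_ABCB_NFIL3", 2.0, "n_ABCB", 2.0),
        ], 0.2),
        _m("ABCC", 1.4, [
            _cmp("PAR_n", "NFIL3_n", "ka_ABCC_PAR", 2.5,
                 "ki_ABCC_NFIL3", 1.6, "n_ABCC", 2.0),
        ], 0.2),
        _m("UGT1A1", 1.0, [
            _act("PAR_n", "ka_UGT1A1_PAR", 2.0, "n_UGT1A1_PAR", 2.0),
            _inh("NR1D_n", "ki_UGT1A1_NR1D", 2.5, "n_UGT1A1_NR1D", 2.0),
        ], 0.2),
    ]
    proteins = [
        _tr("ARNTL_c", "ARNTL", 0.6, 0.25),
        _tr("CLOCK_c", "CLOCK", 0.6, 0.25),
        _cx("CB_c", ["ARNTL_c", "CLOCK_c"], 0.4, 0.25, "dp_CBc"),
        _imp("CB", "CB_c", 0.3, 0.25, "d_x2"),
        _tr("PER_c", "PER", 0.6, 0.3),
        _tr("CRY_c", "CRY", 0.6, 0.3),
        _cx("PC_c", ["PER_c", "CRY_c"], 0.4, 0.25, "dp_PCc"),
        _imp("PC", "PC_c", 0.3, 0.25, "d_x1"),
        _tr("NR1D_n", "NR1D", 0.6, 0.2, "d_x5"),
        _tr("ROR_n", "ROR", 0.6, 0.2, "d_x6"),
        _tr("PAR_n", "PAR", 0.6, 0.2),
        _tr("NFIL3_n", "NFIL3", 0.6, 0.2),
        _tr("PPARA_n", "PPARA", 0.6, 0.2),
    ]
    cfg = {"mrnas": mrnas, "proteins": proteins}
    _override_rates(cfg, _DEFAULT_RATES)
    return cfg


def load_topology(path) -> dict:
    """Load a topology config from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TopologyError("topology config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

class _ParamRegistry:
    def __init__(self):
        self.names: list = []
        self.defaults: list = []
        self._seen: dict = {}

    def add(self, entry) -> int:
        """Register a [name, default] pair; returns the flat index."""
        try:
            name, default = entry
        except (TypeError, ValueError) as exc:
            raise TopologyError(
                f"parameter entry must be a [name, value] pair, got {entry!r}"
            ) from exc
        default = float(default)
        if name in self._seen:
            idx = self._seen[name]
            if self.defaults[idx] != default:
                raise TopologyError(
                    f"parameter {name!r} registered twice with different "
                    f"defaults ({self.defaults[idx]} vs {default})")
            return idx
        idx = len(self.names)
        self._seen[name] = idx
        self.names.append(name)
        self.defaults.append(default)
        return idx


class ODESystem:
    """Compiled transcription-translation network.

    Attributes
    ----------
    species : list of str
        State-vector layout: all mRNAs first, then proteins.
    mrna_names, protein_names : list of str
    default_parameters : ClockParameters
    zeitgeber_targets : list of str
        Genes whose maximal transcription rate responds to forcing.
    """

    def __init__(self, topology: dict):
        self.topology = copy.deepcopy(topology)
        self._compile()

    # -- public API ----------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species: {name!r}") from None

    def rhs(self, t, y, params: ParameterSet | np.ndarray,
            schedule: ZeitgeberSchedule | None = None):
        """Evaluate dy/dt at time ``t`` and state ``y``."""
        p = params.as_array() if isinstance(params, ParameterSet) else np.asarray(params, float)
        zf = (None if schedule is None or schedule.is_trivial()
              else schedule.factor)
        return self._rhs(t, np.asarray(y, float), p, zf)

    def make_rhs(self, params: ParameterSet | np.ndarray,
                 schedule: ZeitgeberSchedule | None = None):
        """Bind parameters/schedule; returns ``f(t, y) -> dy/dt`` for solvers."""
        p = params.as_array() if isinstance(params, ParameterSet) else np.asarray(params, float).copy()
        if p.size != len(self.default_parameters):
            raise ValueError("parameter vector has wrong length")
        zf = (None if schedule is None or schedule.is_trivial()
              else schedule.factor)
        rhs = self._rhs
        return lambda t, y: rhs(t, y, p, zf)

    # -- compilation ---------------------------------------------------------
    def _compile(self):
        cfg = self.topology
        for key in ("mrnas", "proteins"):
            if key not in cfg or not isinstance(cfg[key], list):
                raise TopologyError(f"topology config must list {key!r}")

        mrna_names = [m.get("name") for m in cfg["mrnas"]]
        protein_names = [p.get("name") for p in cfg["proteins"]]
        names = mrna_names + protein_names
        if any(n is None for n in names):
            raise TopologyError("every species entry needs a 'name'")
        dups = sorted({n for n in names if names.count(n) > 1})
        if dups:
            raise TopologyError(f"duplicated species name(s): {dups}")

        self.mrna_names = mrna_names
        self.protein_names = protein_names
        self.species = names
        self._index = {n: i for i, n in enumerate(names)}
        reg = _ParamRegistry()
        n_sp = len(names)

        lines = ["def _rhs(t, y, p, zf):",
                 "    dy = np.zeros(%d)" % n_sp]
        # clipped state values for kinetic terms (solver may undershoot 0)
        for i, n in enumerate(names):
            lines.append(f"    s{i} = y[{i}] if y[{i}] > 0.0 else 0.0")

        self.zeitgeber_targets = []
        for m in cfg["mrnas"]:
            gi = self._index[m["name"]]
            iv = reg.add(m["vmax"])
            idm = reg.add(m["degradation"])
            vexpr = f"p[{iv}]"
            if m.get("zeitgeber_target", False):
                self.zeitgeber_targets.append(m["name"])
                vexpr = (f"(p[{iv}] if zf is None else "
                         f"p[{iv}]*zf(t, {m['name']!r}))")
            act_factors, inh_factors = [], []
            for term in m.get("regulation", []):
                ttype = term.get("type")
                if ttype in ("activate", "inhibit"):
                    rname = term.get("regulator")
                    if rname not in self._index:
                        raise TopologyError(
                            f"unknown regulator {rname!r} for mRNA {m['name']!r}")
                    ri = self._index[rname]
                    ik = reg.add(term["k"])
                    ih = reg.add(term["n"])
                    h = f"(s{ri}/p[{ik}])**p[{ih}]"
                    if ttype == "activate":
                        act_factors.append(f"(({h})/(1.0+({h})))")
                    else:
                        inh_factors.append(f"(1.0/(1.0+({h})))")
                elif ttype == "compete":
                    aname, iname = term.get("activator"), term.get("inhibitor")
                    for nm in (aname, iname):
                        if nm not in self._index:
                            raise TopologyError(
                                f"unknown regulator {nm!r} for mRNA {m['name']!r}")
                    ai, ii = self._index[aname], self._index[iname]
                    ika = reg.add(term["ka"])
                    iki = reg.add(term["ki"])
                    ih = reg.add(term["n"])
                    ha = f"(s{ai}/p[{ika}])**p[{ih}]"
                    hi = f"(s{ii}/p[{iki}])**p[{ih}]"
                    act_factors.append(f"(({ha})/(1.0+({ha})+({hi})))")
                else:
                    raise TopologyError(
                        f"unknown regulation type {ttype!r} on mRNA {m['name']!r}")
            # basal fraction keeps a floor under the activator drive so the
            # network cannot collapse into a near-extinction attractor
            prod = vexpr
            if act_factors:
                aprod = "*".join(act_factors)
                if "basal" in m:
                    ib = reg.add(m["basal"])
                    prod += f"*(p[{ib}]+(1.0-p[{ib}])*{aprod})"
                else:
                    prod += f"*{aprod}"
            if inh_factors:
                prod += "*" + "*".join(inh_factors)
            lines.append(f"    dy[{gi}] = {prod} - p[{idm}]*y[{gi}]")

        for pr in cfg["proteins"]:
            pi = self._index[pr["name"]]
            kind = pr.get("kind")
            if kind == "translate":
                mn = pr.get("mrna")
                if mn not in mrna_names:
                    raise TopologyError(
                        f"protein {pr['name']!r} translates unknown mRNA {mn!r}")
                mi = self._index[mn]
                iktl = reg.add(pr["ktl"])
                idg = reg.add(pr["deg"])
                if "circ_amp" in pr:
                    iamp = reg.add(pr["circ_amp"])
                    iph = reg.add(pr["circ_phase"])
                    dexpr = (f"p[{idg}]*(1.0+p[{iamp}]*math.cos("
                             f"6.283185307179586*(t-p[{iph}])/{CLOCK_PERIOD_H}))")
                else:
                    dexpr = f"p[{idg}]"
                lines.append(f"    dy[{pi}] += p[{iktl}]*s{mi} - ({dexpr})*y[{pi}]")
            elif kind == "import":
                src = pr.get("source")
                if src not in protein_names:
                    raise TopologyError(
                        f"import step {pr['name']!r} source {src!r} is not a "
                        f"declared protein")
                si = self._index[src]
                iki = reg.add(pr["kimp"])
                idg = reg.add(pr["deg"])
                lines.append(f"    imp = p[{iki}]*s{si}")
                lines.append(f"    dy[{pi}] += imp - p[{idg}]*y[{pi}]")
                lines.append(f"    dy[{si}] -= imp")
            elif kind == "complex":
                partners = pr.get("partners", [])
                if len(partners) != 2:
                    raise TopologyError(
                        f"complex {pr['name']!r} needs exactly two partners")
                for nm in partners:
                    if nm not in protein_names:
                        raise TopologyError(
                            f"complex {pr['name']!r} partner {nm!r} is not a "
                            f"declared protein")
                ai, bi = (self._index[nm] for nm in partners)
                ika = reg.add(pr["kass"])
                idg = reg.add(pr["deg"])
                lines.append(f"    assoc = p[{ika}]*s{ai}*s{bi}")
                lines.append(f"    dy[{pi}] += assoc - p[{idg}]*y[{pi}]")
                lines.append(f"    dy[{ai}] -= assoc")
                lines.append(f"    dy[{bi}] -= assoc")
            else:
                raise TopologyError(
                    f"unknown protein kind {kind!r} for {pr.get('name')!r}")
        lines.append("    return dy")

        src = "\n".join(lines)
        ns = {"np": np, "math": __import__("math")}
        exec(compile(src, "<network-rhs>", "exec"), ns)  # noqa: S102 - trusted codegen
        self._rhs = ns["_rhs"]
        self._rhs_source = src
        self.default_parameters = ClockParameters(reg.names, reg.defaults)


def build_network(topology: dict | str | None = None) -> ODESystem:
    """Validate a topology config and compile it to an :class:`ODESystem`.

    ``topology`` may be a config dict, a path to a YAML file, or None for
    the default wild-type network.
    """
    if topology is None:
        topology = default_topology()
    elif isinstance(topology, str):
        topology = load_topology(topology)
    return ODESystem(topology)
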