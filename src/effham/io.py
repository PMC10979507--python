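"""On-disk containers: HDF5 structure/target archives, model files, Molden export.

Container schema (HDF5): one group per structure, named ``s<k>``, holding

    symbols    : fixed-length ASCII element symbols
    coordinates: (n_atoms, 3) float64, Å
    net_charge : int attribute
    hamiltonian / eigenvalues / charges : optional float64 datasets (Hartree / e)

Model files carry the weight vector per block family plus the radial-basis
spec, the basis layout and the element list, so a prediction run needs only
the model file and a geometry.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from .basis import BasisLayout
from .features import RadialBasisSpec
from .geometry import MolecularGeometry
from .hamiltonian import BlockKey, ModelWeights
from .training import LossConfig, TrainedModel


def save_structures(path, geometries, targets=None) -> None:
    """Write geometries (and optional TrainingTarget data) to a container."""
    with h5py.File(path, "w") as fh:
        for k, geo in enumerate(geometries):
            g = fh.create_group(f"s{k}")
            g.create_dataset("symbols", data=np.array(geo.symbols, dtype="S2"))
            g.create_dataset("coordinates", data=geo.coordinates)
            g.attrs["net_charge"] = geo.net_charge
            if targets is not None:
                if targets.hamiltonians is not None:
                    g.create_dataset("hamiltonian", data=targets.hamiltonians[k])
                if targets.eigenvalues is not None:
                    g.create_dataset("eigenvalues", data=targets.eigenvalues[k])
                if targets.charges is not None:
                    g.create_dataset("charges", data=targets.charges[k])
        if targets is not None:
            fh.attrs["target_kind"] = targets.kind
            if targets.n_select:
                fh.attrs["n_select"] = targets.n_select


def load_structures(path):
    """Read a container; returns (geometries, TrainingTarget or None)."""
    from .training import TrainingTarget
    geometries, hams, eigs, chgs = [], [], [], []
    with h5py.File(path, "r") as fh:
        names = sorted((n for n in fh if n.startswith("s")),
                       key=lambda n: int(n[1:]))
        for name in names:
            g = fh[name]
            symbols = tuple(s.decode() for s in g["symbols"][()])
            geometries.append(MolecularGeometry(symbols, g["coordinates"][()],
                                                int(g.attrs.get("net_charge", 0))))
            for key, acc in (("hamiltonian", hams), ("eigenvalues", eigs),
                             ("charges", chgs)):
                if key in g:
                    acc.append(g[key][()])
        kind = fh.attrs.get("target_kind")
        n_select = int(fh.attrs["n_select"]) if "n_select" in fh.attrs else None
    if kind is None:
        return geometries, None
    target = TrainingTarget(str(kind),
                            hamiltonians=hams or None,
                            eigenvalues=eigs or None,
                            charges=chgs or None,
                            n_select=n_select)
    return geometries, target


def _spec_dict(spec: RadialBasisSpec) -> dict:
    return {"n_max": spec.n_max, "l_max": spec.l_max,
            "gaussian_width": spec.gaussian_width, "cutoff": spec.cutoff,
            "taper_width": spec.taper_width}


def spec_hash(spec: RadialBasisSpec, layout: BasisLayout, species) -> str:
    payload = json.dumps({"spec": _spec_dict(spec),
                          "layout": {k: list(map(list, v))
                                     for k, v in layout.shells_per_element.items()},
                          "species": list(species)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_model(path, model: TrainedModel) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["spec"] = json.dumps(_spec_dict(model.spec))
        fh.attrs["layout"] = json.dumps({k: list(map(list, v)) for k, v in
                                         model.layout.shells_per_element.items()})
        fh.attrs["species"] = json.dumps(list(model.species))
        fh.attrs["lam_max"] = model.lam_max
        fh.attrs["mode"] = model.config.mode
        fh.attrs["spec_hash"] = spec_hash(model.spec, model.layout, model.species)
        fh.create_dataset("loss_history", data=np.asarray(model.loss_history))
        wg = fh.create_group("weights")
        for key, w in model.weights.weights.items():
            name = json.dumps([key.kind, list(key.species), key.a, key.b,
                               key.tau, key.lam])
            wg.create_dataset(name, data=w)


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as fh:
        spec = RadialBasisSpec(**json.loads(fh.attrs["spec"]))
        layout = BasisLayout({k: tuple(map(tuple, v)) for k, v in
                              json.loads(fh.attrs["layout"]).items()})
        species = tuple(json.loads(fh.attrs["species"]))
        lam_max = int(fh.attrs["lam_max"])
        config = LossConfig(mode=str(fh.attrs["mode"]))
        history = list(fh["loss_history"][()])
        weights = {}
        for name, ds in fh["weights"].items():
            kind, sp, a, b, tau, lam = json.loads(name)
            weights[BlockKey(kind, tuple(sp), a, b, tau, lam)] = ds[()]
    return TrainedModel(ModelWeights(weights), history, config, spec, layout,
                        species, lam_max)


# --- Molden export (cosmetic MO visualization on STO-3G radial parts) -------

# STO-3G exponents/contractions (standard published values)
_STO3G = {
    "H": [("s", [(3.42525091, 0.15432897), (0.62391373, 0.53532814),
                 (0.16885540, 0.44463454)])],
    "C": [("s", [(71.6168370, 0.15432897), (13.0450960, 0.53532814),
                 (3.53051220, 0.44463454)]),
          ("s", [(2.94124940, -0.09996723), (0.68348310, 0.39951283),
                 (0.22228990, 0.70011547)]),
          ("p", [(2.94124940, 0.15591627), (0.68348310, 0.60768372),
                 (0.22228990, 0.39195739)])],
}


def write_molden(path, geometry: MolecularGeometry, solution) -> None:
    """Write MOs in Molden format using STO-3G radial parts for display.

    The effective Hamiltonian's basis is implicit; this export only serves
    qualitative orbital inspection and is not used in any computation.
    """
    from .constants import ATOMIC_NUMBERS
    lines = ["[Molden Format]", "[Atoms] Angs"]
    for k, (sym, xyz) in enumerate(zip(geometry.symbols, geometry.coordinates), 1):
        lines.append(f"{sym} {k} {ATOMIC_NUMBERS[sym]} "
                     f"{xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    lines.append("[GTO]")
    for k, sym in enumerate(geometry.symbols, 1):
        lines.append(f"{k} 0")
        for shell_type, prims in _STO3G[sym]:
            lines.append(f"{shell_type} {len(prims)} 1.00")
            for expo, coef in prims:
                lines.append(f"{expo:.8f} {coef:.8f}")
        lines.append("")
    lines.append("[MO]")
    for n in range(solution.energies.size):
        lines.append(f"Sym= A\nEne= {solution.energies[n]:.8f}\nSpin= Alpha")
        lines.append(f"Occup= {solution.occupations[n]:.6f}")
        for mu, c in enumerate(solution.coefficients[:, n], 1):
            lines.append(f"{mu} {c:.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
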