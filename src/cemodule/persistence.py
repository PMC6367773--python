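"""HDF5 container for factorization results (factors + registries + trace)."""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np

from .datatypes import FactorizationResult, ValidationError

__all__ = ["save_result", "load_result"]

_STR = h5py.string_dtype(encoding="utf-8")


def save_result(result: FactorizationResult, path) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in (
            ("W", result.W),
            ("H1", result.H1),
            ("H2", result.H2),
            ("H3", result.H3),
            ("objective_trace", np.asarray(result.objective_trace, dtype=float)),
        ):
            # track_times=False keeps files byte-identical across reruns
            f.create_dataset(name, data=arr, track_times=False)
        for name, ids in (
            ("lnc_ids", result.lnc_ids),
            ("mir_ids", result.mir_ids),
            ("mrna_ids", result.mrna_ids),
        ):
            if ids is not None:
                f.create_dataset(name, data=np.array(ids, dtype=object),
                                 dtype=_STR, track_times=False)
        f.attrs["iterations_run"] = result.iterations_run
        f.attrs["converged"] = result.converged
        f.attrs["seed_used"] = result.seed_used


def load_result(path) -> FactorizationResult:
    with h5py.File(path, "r") as f:
        def ids(name) -> Optional[list]:
            if name not in f:
                return None
            return [x.decode() if isinstance(x, bytes) else str(x) for x in f[name][()]]

        try:
            return FactorizationResult(
                W=f["W"][()],
                H1=f["H1"][()],
                H2=f["H2"][()],
                H3=f["H3"][()],
                objective_trace=list(f["objective_trace"][()]),
                iterations_run=int(f.attrs["iterations_run"]),
                converged=bool(f.attrs["converged"]),
                seed_used=int(f.attrs["seed_used"]),
                lnc_ids=ids("lnc_ids"),
                mir_ids=ids("mir_ids"),
                mrna_ids=ids("mrna_ids"),
            )
        except KeyError as exc:
            raise ValidationError(f"{path} is not a factorization result container: {exc}")
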