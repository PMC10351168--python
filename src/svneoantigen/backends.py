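"""MHC class I binding backends.

Binding prediction itself is out of scope: the external predictors
(netMHCpan for affinity, netMHCstabPan for complex stability) are driven
through thin subprocess adapters that batch peptides, parse the tabular
output by header, and map rows back positionally.  A deterministic mock
backend hashing (peptide, allele, seed) serves tests and any environment
without the binaries; it supports "always-bind" and "never-bind" modes for
round-trip checks.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .model import BindingCall


class BackendUnavailableError(RuntimeError):
    pass


class BindingBackend(ABC):
    """Contract: one deterministic BindingCall per peptide x allele."""

    name: str = "abstract"

    @abstractmethod
    def predict(self, peptides: Sequence[str],
                alleles: Sequence[str]) -> list[BindingCall]:
        ...


def _unit_hash(*parts) -> float:
    """Uniform deviate in [0, 1) from a stable hash of the parts."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2.0 ** 64


class MockBindingBackend(BindingBackend):
    """Seeded hash-based predictor.

    mode "hash": ic50 uniform in [1, 50000) nM, rank uniform in [0, 100).
    mode "always": every call binds (ic50 < 500 nM, rank < 2.0).
    mode "never": no call binds (ic50 >= 5000 nM, rank >= 50).
    """

    name = "mock"

    def __init__(self, seed: int = 0, mode: str = "hash"):
        if mode not in ("hash", "always", "never"):
            raise ValueError(f"unknown mock mode {mode!r}")
        self.seed = seed
        self.mode = mode

    def _call(self, peptide: str, allele: str) -> BindingCall:
        u1 = _unit_hash(self.seed, peptide, allele, "ic50")
        u2 = _unit_hash(self.seed, peptide, allele, "rank")
        if self.mode == "always":
            ic50, rank = 1.0 + u1 * 498.0, u2 * 1.99
        elif self.mode == "never":
            ic50, rank = 5000.0 + u1 * 45000.0, 50.0 + u2 * 50.0
        else:
            ic50, rank = 1.0 + u1 * 49999.0, u2 * 100.0
        return BindingCall(peptide=peptide, allele=allele, ic50=ic50, rank=rank)

    def predict(self, peptides: Sequence[str],
                alleles: Sequence[str]) -> list[BindingCall]:
        return [self._call(p, a) for p in peptides for a in alleles]


@dataclass(frozen=True)
class StabilityCall:
    peptide: str
    allele: str
    half_life_hours: float
    rank: float


class MockStabilityBackend:
    """Deterministic stand-in for the external stability predictor."""

    name = "mock-stab"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def predict(self, peptides: Sequence[str],
                alleles: Sequence[str]) -> list[StabilityCall]:
        return [
            StabilityCall(p, a,
                          half_life_hours=_unit_hash(self.seed, p, a, "thalf") * 12.0,
                          rank=_unit_hash(self.seed, p, a, "stabrank") * 100.0)
            for p in peptides for a in alleles
        ]


# ---------------------------------------------------------------------------
# External binary adapters


def _find_columns(header_fields: list[str], wanted: dict[str, list[str]]) -> dict[str, int]:
    out: dict[str, int] = {}
    for key, aliases in wanted.items():
        for alias in aliases:
            if alias in header_fields:
                out[key] = header_fields.index(alias)
                break
        else:
            raise ValueError(f"column {aliases} not found in predictor output header")
    return out


def parse_netmhcpan_output(text: str) -> list[BindingCall]:
    """Parse netMHCpan long-format (-BA) output by header columns."""
    calls: list[BindingCall] = []
    cols: dict[str, int] | None = None
    for line in text.splitlines():
        fields = line.split()
        if not fields or line.lstrip().startswith("#"):
            continue
        if fields[0] == "Pos":
            cols = _find_columns(fields, {
                "allele": ["MHC", "HLA", "Allele"],
                "peptide": ["Peptide"],
                "ic50": ["Aff(nM)", "Affinity(nM)"],
                "rank": ["%Rank_BA", "%Rank", "Rank"],
            })
            continue
        if cols is None or not fields[0].isdigit():
            continue
        calls.append(BindingCall(
            peptide=fields[cols["peptide"]],
            allele=fields[cols["allele"]],
            ic50=float(fields[cols["ic50"]]),
            rank=float(fields[cols["rank"]]),
        ))
    return calls


def parse_netmhcstabpan_output(text: str) -> list[StabilityCall]:
    """Parse netMHCstabPan default output by header columns."""
    calls: list[StabilityCall] = []
    cols: dict[str, int] | None = None
    for line in text.splitlines():
        fields = line.split()
        if not fields or line.lstrip().startswith("#"):
            continue
        if fields[0] == "Pos":
            cols = _find_columns(fields, {
                "allele": ["MHC", "HLA", "Allele"],
                "peptide": ["Peptide"],
                "thalf": ["Thalf(h)", "Pred"],
                "rank": ["%Rank_Stab", "%Rank", "Rank"],
            })
            continue
        if cols is None or not fields[0].isdigit():
            continue
        calls.append(StabilityCall(
            peptide=fields[cols["peptide"]],
            allele=fields[cols["allele"]],
            half_life_hours=float(fields[cols["thalf"]]),
            rank=float(fields[cols["rank"]]),
        ))
    return calls


class _ExternalAdapter:
    executable: str = ""
    extra_args: tuple[str, ...] = ()

    def __init__(self, executable: str | None = None):
        if executable is not None:
            self.executable = executable

    def _run(self, peptides: Sequence[str], allele: str) -> str:
        exe = shutil.which(self.executable)
        if exe is None:
            raise BackendUnavailableError(
                f"external predictor '{self.executable}' not found on PATH; "
                f"install it or use the mock backend (--backend mock)")
        with tempfile.TemporaryDirectory() as tmp:
            pep_file = Path(tmp) / "peptides.txt"
            pep_file.write_text("\n".join(peptides) + "\n")
            proc = subprocess.run(
                [exe, "-p", str(pep_file), "-a", allele, *self.extra_args],
                capture_output=True, text=True, check=True)
        return proc.stdout


class NetMHCpanBackend(_ExternalAdapter, BindingBackend):
    """Adapter around the netMHCpan binary (affinity mode)."""

    name = "netmhcpan"
    executable = "netMHCpan"
    extra_args = ("-BA",)

    def predict(self, peptides: Sequence[str],
                alleles: Sequence[str]) -> list[BindingCall]:
        calls: list[BindingCall] = []
        for allele in alleles:
            parsed = parse_netmhcpan_output(self._run(peptides, allele))
            if len(parsed) != len(peptides):
                raise RuntimeError(
                    f"{self.executable} returned {len(parsed)} rows for "
                    f"{len(peptides)} peptides (allele {allele}); aborting")
            calls.extend(parsed)
        return calls


class NetMHCstabPanBackend(_ExternalAdapter):
    """Adapter around the netMHCstabPan binary (default parameters)."""

    name = "netmhcstabpan"
    executable = "netMHCstabpan"

    def predict(self, peptides: Sequence[str],
                alleles: Sequence[str]) -> list[StabilityCall]:
        calls: list[StabilityCall] = []
        for allele in alleles:
            parsed = parse_netmhcstabpan_output(self._run(peptides, allele))
            if len(parsed) != len(peptides):
                raise RuntimeError(
                    f"{self.executable} returned {len(parsed)} rows for "
                    f"{len(peptides)} peptides (allele {allele}); aborting")
            calls.extend(parsed)
        return calls


def get_backend(name: str, seed: int = 0, mode: str = "hash") -> BindingBackend:
    if name == "mock":
        return MockBindingBackend(seed=seed, mode=mode)
    if name == "netmhcpan":
        return NetMHCpanBackend()
    raise ValueError(f"unknown binding backend {name!r}")
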