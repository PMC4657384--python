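"""numba-compiled Gillespie direct-method kernel.

Rate laws are lowered to a tiny stack bytecode (see ``expressions``), so one
jitted interpreter serves every network -- elementary and non-elementary
propensities alike.  Per-replicate streams use the counter scheme
``seed = (seed_base + rep) mod 2**32``; ensembles are therefore reproducible
and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .expressions import (
    OP_ADD,
    OP_CONST,
    OP_DIV,
    OP_MUL,
    OP_NEG,
    OP_POW,
    OP_SPECIES,
    OP_SQRT,
    OP_SUB,
)

__all__ = ["CompiledNetwork", "compile_network", "ensemble_states"]


@dataclass(frozen=True)
class CompiledNetwork:
    code: np.ndarray  # int32, opcodes of all reactions, concatenated
    args: np.ndarray  # int32, operand per opcode (species or const index)
    offsets: np.ndarray  # int32, start of each reaction's program
    lengths: np.ndarray  # int32
    consts: np.ndarray  # float64, shared constant pool
    stoich: np.ndarray  # int64 (n_reactions, n_species)
    volume: float


def compile_network(network) -> CompiledNetwork:
    if network.has_prefactor:
        raise ValueError(
            f"network {network.name!r} carries a prefactor; stochastic simulation "
            "is defined only for unprefactored networks (see without_prefactor())"
        )
    order = network.species_order
    code_parts, arg_parts, offsets, lengths = [], [], [], []
    consts: list[float] = []
    for rxn in network.reactions:
        ops, args, rconsts = network.rate_expression(rxn).bytecode(order)
        args = args.copy()
        args[ops == OP_CONST] += len(consts)
        consts.extend(rconsts.tolist())
        offsets.append(sum(lengths))
        lengths.append(len(ops))
        code_parts.append(ops)
        arg_parts.append(args)
    stoich = np.zeros((len(network.reactions), len(order)), dtype=np.int64)
    for j, rxn in enumerate(network.reactions):
        for i, sp in enumerate(order):
            stoich[j, i] = rxn.net_change(sp)
    if not code_parts:  # reactionless network: every state is absorbing
        code_parts = [np.empty(0, dtype=np.int32)]
        arg_parts = [np.empty(0, dtype=np.int32)]
    return CompiledNetwork(
        np.concatenate(code_parts).astype(np.int32),
        np.concatenate(arg_parts).astype(np.int32),
        np.asarray(offsets, dtype=np.int32),
        np.asarray(lengths, dtype=np.int32),
        np.asarray(consts, dtype=np.float64),
        stoich,
        float(network.volume),
    )


@njit(cache=False)
def _eval_program(code, args, start, length, consts, conc, stack):
    sp = 0
    for i in range(start, start + length):
        op = code[i]
        if op == OP_CONST:
            stack[sp] = consts[args[i]]
            sp += 1
        elif op == OP_SPECIES:
            stack[sp] = conc[args[i]]
            sp += 1
        elif op == OP_ADD:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] + stack[sp]
        elif op == OP_SUB:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] - stack[sp]
        elif op == OP_MUL:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] * stack[sp]
        elif op == OP_DIV:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] / stack[sp]
        elif op == OP_POW:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] ** stack[sp]
        elif op == OP_SQRT:
            stack[sp - 1] = np.sqrt(stack[sp - 1])
        elif op == OP_NEG:
            stack[sp - 1] = -stack[sp - 1]
    return stack[0]


@njit(cache=False)
def _mix_seed(counter):
    """SplitMix64 scramble of the replicate counter.

    Consecutive integers seed Mersenne Twister streams whose early outputs
    are weakly cross-correlated, which biases ensemble moments; hashing the
    counter first decorrelates the streams while keeping the scheme
    deterministic and order-independent.
    """
    z = np.uint64(counter) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return np.uint32(z & np.uint64(0xFFFFFFFF))


@njit(cache=False)
def _run_ensemble(
    code, args, offsets, lengths, consts, stoich, volume, init, rec_times, n_reps, seed_base
):
    n_rxn, n_sp = stoich.shape
    n_rec = rec_times.shape[0]
    out = np.zeros((n_reps, n_rec, n_sp), dtype=np.int64)
    stack = np.empty(64, dtype=np.float64)
    conc = np.empty(n_sp, dtype=np.float64)
    a = np.empty(n_rxn, dtype=np.float64)
    status = 0
    for rep in range(n_reps):
        np.random.seed(_mix_seed(seed_base + rep))
        counts = init.astype(np.float64)
        t = 0.0
        ri = 0
        while ri < n_rec:
            a0 = 0.0
            for j in range(n_rxn):
                for i in range(n_sp):
                    conc[i] = counts[i] / volume
                aj = volume * _eval_program(code, args, offsets[j], lengths[j], consts, conc, stack)
                if aj < 0.0:
                    if aj < -1e-9:
                        status = 1
                    aj = 0.0
                a[j] = aj
                a0 += aj
            if a0 <= 0.0 or status != 0:
                break  # absorbing state: remaining records keep current counts
            t_next = t + np.random.exponential(1.0) / a0
            while ri < n_rec and rec_times[ri] < t_next:
                for i in range(n_sp):
                    out[rep, ri, i] = np.int64(counts[i] + 0.5)
                ri += 1
            if ri == n_rec:
                break
            u = np.random.random() * a0
            acc = 0.0
            j_sel = n_rxn - 1
            for j in range(n_rxn):
                acc += a[j]
                if u < acc:
                    j_sel = j
                    break
            for i in range(n_sp):
                counts[i] += stoich[j_sel, i]
            t = t_next
        while ri < n_rec:
            for i in range(n_sp):
                out[rep, ri, i] = np.int64(counts[i] + 0.5)
            ri += 1
        if status != 0:
            break
    return out, status


def ensemble_states(
    compiled: CompiledNetwork,
    init_counts: np.ndarray,
    rec_times: np.ndarray,
    n_reps: int,
    seed_base: int,
) -> np.ndarray:
    """Counts at each record time for every replicate: (reps, times, species)."""
    out, status = _run_ensemble(
        compiled.code,
        compiled.args,
        compiled.offsets,
        compiled.lengths,
        compiled.consts,
        compiled.stoich,
        compiled.volume,
        np.asarray(init_counts, dtype=np.int64),
        np.asarray(rec_times, dtype=np.float64),
        int(n_reps),
        int(seed_base) % 2**31,
    )
    if status != 0:
        raise ValueError("a propensity evaluated to a negative value during SSA")
    return out
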