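"""Generation of differential-conditioning trial sequences.

The experimental session has four blocks presented in fixed order:
habituation (HAB), two acquisition blocks (ACQ1, ACQ2) and extinction
(EXT).  Four Gabor cues are shown: the conditioned stimulus (CSP) and
three generalization stimuli of decreasing similarity (GS1..GS3).  Cue
order is randomized per block under two constraints:

* the same cue never appears more than twice in a row within a block;
* the first six CSP presentations of ACQ1 are "boosted": consecutive
  CSPs among those six are separated by at most two GS trials.

US reinforcement follows a 100%/50% schedule: the first six CSP trials
of ACQ1 are always paired with the shock, after which exactly half of
the remaining ACQ1 CSPs and half of the ACQ2 CSPs are paired.  No US is
delivered during HAB or EXT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CUES = ("CSP", "GS1", "GS2", "GS3")
BLOCKS = ("HAB", "ACQ1", "ACQ2", "EXT")

#: number of presentations of each cue per block
REPS_PER_BLOCK = {"HAB": 8, "ACQ1": 12, "ACQ2": 12, "EXT": 12}

DESIGN_COLUMNS = ["participant", "trial", "block", "cue", "paired"]


@dataclass(frozen=True)
class DesignConstraints:
    """Constants of the conditioning design.

    ``max_run`` is the maximum number of consecutive identical cues,
    ``n_boosted`` the number of initial 100%-reinforced CSP trials in
    ACQ1, and ``max_gap`` the maximum number of GS trials allowed
    between consecutive boosted CSPs.
    """

    cues: tuple[str, ...] = CUES
    reps: dict = field(default_factory=lambda: dict(REPS_PER_BLOCK))
    max_run: int = 2
    n_boosted: int = 6
    max_gap: int = 2
    max_retries: int = 10_000

    @property
    def n_trials(self) -> int:
        return len(self.cues) * sum(self.reps[b] for b in BLOCKS)


def _max_run_ok(seq: list[str], max_run: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


def _boost_spacing_ok(seq: list[str], n_boosted: int, max_gap: int) -> bool:
    """At most ``max_gap`` non-CSP trials between consecutive CSPs among
    the first ``n_boosted`` CSP presentations (and before the first)."""
    positions = [i for i, c in enumerate(seq) if c == "CSP"][:n_boosted]
    if len(positions) < n_boosted:
        return False
    prev = -1
    for pos in positions:
        if pos - prev - 1 > max_gap:
            return False
        prev = pos
    return True


def _shuffle_block(rng: np.random.Generator, cues: tuple[str, ...],
                   reps: int, max_run: int, max_retries: int) -> list[str]:
    pool = np.repeat(np.asarray(cues, dtype=object), reps)
    for _ in range(max_retries):
        perm = rng.permutation(pool).tolist()
        if _max_run_ok(perm, max_run):
            return perm
    raise RuntimeError(
        f"could not satisfy max-run={max_run} constraint after {max_retries} retries"
    )


def _acq1_block(rng: np.random.Generator, c: DesignConstraints) -> list[str]:
    """ACQ1 sequence with the boosted-CSP spacing constraint.

    Constructed by proposing a front segment holding the first
    ``n_boosted`` CSPs with gaps of 0..max_gap GS trials, appending the
    shuffled remainder, then validating the whole block.
    """
    gs_cues = [cue for cue in c.cues if cue != "CSP"]
    reps = c.reps["ACQ1"]
    for _ in range(c.max_retries):
        gs_pool = list(np.repeat(np.asarray(gs_cues, dtype=object), reps))
        rng.shuffle(gs_pool)
        front: list[str] = []
        # GS prefix, then boosted CSPs separated by short GS gaps
        for k in range(c.n_boosted + 1):
            if k > 0:
                front.append("CSP")
            if k < c.n_boosted:
                gap = int(rng.integers(0, c.max_gap + 1))
                for _ in range(gap):
                    front.append(gs_pool.pop())
        tail = ["CSP"] * (reps - c.n_boosted) + gs_pool
        rng.shuffle(tail)
        seq = front + tail
        if _max_run_ok(seq, c.max_run) and _boost_spacing_ok(seq, c.n_boosted, c.max_gap):
            return seq
    raise RuntimeError(
        f"could not satisfy ACQ1 constraints after {c.max_retries} retries"
    )


def generate_design(n_participants: int, seed: int,
                    constraints: DesignConstraints | None = None) -> pd.DataFrame:
    """Generate randomized cue sequences for ``n_participants``.

    Returns a tidy table with columns ``participant, trial, block, cue,
    paired`` (one row per trial; trials numbered 1..T across the whole
    session).  Reinforcement is assigned by :func:`assign_reinforcement`
    using a seed derived from ``seed``, so the full schedule is
    deterministic given ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    c = constraints or DesignConstraints()
    ss = np.random.SeedSequence(seed)
    order_seed, reinforce_seed = ss.spawn(2)
    rng = np.random.default_rng(order_seed)

    frames = []
    for p in range(1, n_participants + 1):
        cues: list[str] = []
        blocks: list[str] = []
        for block in BLOCKS:
            if block == "ACQ1":
                seq = _acq1_block(rng, c)
            else:
                seq = _shuffle_block(rng, c.cues, c.reps[block], c.max_run,
                                     c.max_retries)
            cues.extend(seq)
            blocks.extend([block] * len(seq))
        frames.append(pd.DataFrame({
            "participant": p,
            "trial": np.arange(1, len(cues) + 1),
            "block": blocks,
            "cue": cues,
            "paired": 0,
        }))
    design = pd.concat(frames, ignore_index=True)
    return assign_reinforcement(design, seed=int(reinforce_seed.generate_state(1)[0] % (2**31)),
                                constraints=c)


def assign_reinforcement(design: pd.DataFrame, seed: int,
                         constraints: DesignConstraints | None = None) -> pd.DataFrame:
    """Assign the US pairing schedule to a design.

    The first ``n_boosted`` CSP trials of ACQ1 are paired (100%
    reinforcement); of the remaining ACQ1 CSPs and the ACQ2 CSPs exactly
    half are paired, at randomized positions (the 50% rate realized as
    an exact half).  HAB and EXT are never paired.
    """
    c = constraints or DesignConstraints()
    rng = np.random.default_rng(seed)
    out = design.copy()
    out["paired"] = 0
    for p, grp in out.groupby("participant"):
        csp_acq1 = grp.index[(grp.block == "ACQ1") & (grp.cue == "CSP")]
        csp_acq2 = grp.index[(grp.block == "ACQ2") & (grp.cue == "CSP")]
        if len(csp_acq1) == 0 and len(csp_acq2) == 0:
            continue
        boosted = csp_acq1[: c.n_boosted]
        rest1 = csp_acq1[c.n_boosted:]
        if len(rest1) % 2 or len(csp_acq2) % 2:
            raise ValueError(
                f"participant {p}: odd eligible CSP count "
                f"({len(rest1)} post-boost ACQ1, {len(csp_acq2)} ACQ2); malformed design"
            )
        out.loc[boosted, "paired"] = 1
        for idx in (rest1, csp_acq2):
            if len(idx):
                chosen = rng.choice(idx, size=len(idx) // 2, replace=False)
                out.loc[chosen, "paired"] = 1
    return out


def validate_design(design: pd.DataFrame,
                    constraints: DesignConstraints | None = None) -> None:
    """Raise ``ValueError`` if any design invariant is violated."""
    c = constraints or DesignConstraints()
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise ValueError(f"missing column {col!r}")
    for p, grp in design.groupby("participant"):
        grp = grp.sort_values("trial")
        if not np.array_equal(grp.trial.to_numpy(), np.arange(1, len(grp) + 1)):
            raise ValueError(f"participant {p}: trials not 1..T")
        if len(grp) != c.n_trials:
            raise ValueError(f"participant {p}: expected {c.n_trials} trials")
        for block in BLOCKS:
            sub = grp[grp.block == block]
            counts = sub.cue.value_counts()
            for cue in c.cues:
                if counts.get(cue, 0) != c.reps[block]:
                    raise ValueError(
                        f"participant {p}, block {block}: cue {cue} appears "
                        f"{counts.get(cue, 0)} times, expected {c.reps[block]}"
                    )
            if not _max_run_ok(sub.cue.tolist(), c.max_run):
                raise ValueError(f"participant {p}, block {block}: cue run > {c.max_run}")
        acq1 = grp[grp.block == "ACQ1"]
        if not _boost_spacing_ok(acq1.cue.tolist(), c.n_boosted, c.max_gap):
            raise ValueError(f"participant {p}: boosted CSP spacing violated")
        csp1 = acq1[acq1.cue == "CSP"]
        if not (csp1.paired.to_numpy()[: c.n_boosted] == 1).all():
            raise ValueError(f"participant {p}: first {c.n_boosted} ACQ1 CSPs not all paired")
        bad = grp[(grp.paired == 1)
                  & ~((grp.cue == "CSP") & grp.block.isin(["ACQ1", "ACQ2"]))]
        if len(bad):
            raise ValueError(f"participant {p}: US paired outside acquisition CSP trials")
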