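"""Double-sided two-way ranging (DS-TWR) between two UWB nodes.

A single request-reply round measures the round-trip time on one clock and
the reply delay on the other, so the distance estimate inherits the product
of clock-rate offset and reply delay as error.  Adding a second round in the
opposite direction lets the two rounds compensate: with rounds
(t_round1, t_reply1) timed on A/B and (t_round2, t_reply2) on B/A,

    t_p = (t_round1·t_round2 − t_reply1·t_reply2)
          / (t_round1 + t_round2 + t_reply1 + t_reply2)

recovers the one-way flight time exactly for ideal clocks regardless of
reply asymmetry, and to first order cancels clock drift.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MalformedExchangeError

#: speed of light in air, cm/s
SPEED_OF_LIGHT_AIR_CM_S = 2.99702547e10

__all__ = ["TwrExchange", "RangeResult", "ds_twr_distance", "ss_twr_distance",
           "SPEED_OF_LIGHT_AIR_CM_S"]


@dataclass(frozen=True)
class TwrExchange:
    """Six event timestamps (s) of one DS-TWR exchange, on their local clocks.

    T1/T4/T5 are read on node A's clock (send, receive, send); T2/T3/T6 on
    node B's (receive, send, receive).  Only the four differences below enter
    the range computation, so clock *offsets* cancel by construction; clock
    *rates* do not, which is what the double-sided form compensates.
    """

    T1: float
    T2: float
    T3: float
    T4: float
    T5: float
    T6: float

    @property
    def t_round1(self) -> float:
        return self.T4 - self.T1

    @property
    def t_reply1(self) -> float:
        return self.T3 - self.T2

    @property
    def t_round2(self) -> float:
        return self.T6 - self.T3

    @property
    def t_reply2(self) -> float:
        return self.T5 - self.T4

    # measured reply may exceed measured round by drift skew: at flight times
    # near zero, a fast responder clock against a slow initiator clock shifts
    # the comparison by (rate difference) x reply.  1000 ppm is far beyond
    # any real crystal, so a larger excess marks a malformed exchange.
    _DRIFT_MARGIN = 1e-3

    def validate(self) -> None:
        for k, (rnd, rep) in enumerate(((self.t_round1, self.t_reply1),
                                        (self.t_round2, self.t_reply2)), start=1):
            if rep < 0.0 or rnd < rep * (1.0 - self._DRIFT_MARGIN):
                raise MalformedExchangeError(
                    f"round {k} timing invalid: round={rnd}, reply={rep}")


@dataclass(frozen=True)
class RangeResult:
    """One-way propagation time (s) and the derived distance (cm)."""

    tp: float
    dis: float
    c: float = SPEED_OF_LIGHT_AIR_CM_S


def ds_twr_distance(x: TwrExchange, c: float = SPEED_OF_LIGHT_AIR_CM_S) -> RangeResult:
    """Distance (cm) from a double-sided exchange.

    Dis = c · (t_round1·t_round2 − t_reply1·t_reply2)
            / (t_round1 + t_round2 + t_reply1 + t_reply2).

    Exact for ideal clocks at any reply asymmetry; the residual error under
    clock drift is second-order in the drift, versus first-order for the
    single-sided estimate.
    """
    x.validate()
    denom = x.t_round1 + x.t_round2 + x.t_reply1 + x.t_reply2
    if denom <= 0:
        raise MalformedExchangeError(f"nonpositive time sum {denom}")
    tp = (x.t_round1 * x.t_round2 - x.t_reply1 * x.t_reply2) / denom
    return RangeResult(tp=tp, dis=c * tp, c=c)


def ss_twr_distance(x: TwrExchange, c: float = SPEED_OF_LIGHT_AIR_CM_S) -> RangeResult:
    """Single-sided estimate c·(t_round1 − t_reply1)/2 from the same exchange.

    Provided as the comparison baseline: its error grows linearly with the
    clock-rate difference times the reply delay.
    """
    x.validate()
    tp = 0.5 * (x.t_round1 - x.t_reply1)
    return RangeResult(tp=tp, dis=c * tp, c=c)
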