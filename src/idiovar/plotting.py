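"""IRF plotting: point response with its bootstrap confidence band."""

from __future__ import annotations

from .dynamics import IrfResult

__all__ = ["plot_irf"]


def plot_irf(irf: IrfResult, ax=None, cumulative: bool = False):
    """Plot an impulse response over its horizon, dashed 95% band if present.

    Returns the matplotlib axes.
    """
    import matplotlib

    if matplotlib.get_backend().lower() not in ("agg", "module://matplotlib_inline.backend_inline"):
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    y = irf.cumulative if cumulative else irf.point
    lo = irf.cum_lower if cumulative else irf.lower
    hi = irf.cum_upper if cumulative else irf.upper
    ax.plot(irf.horizons, y, color="black", lw=1.5)
    if lo is not None:
        ax.plot(irf.horizons, lo, color="red", ls="--", lw=1.0)
        ax.plot(irf.horizons, hi, color="red", ls="--", lw=1.0)
    ax.axhline(0.0, color="grey", lw=0.8)
    kind = "cumulative response" if cumulative else "response"
    ax.set_xlabel("days")
    ax.set_ylabel(f"{kind} of {irf.response}")
    ax.set_title(
        f"Impulse: {irf.impulse} (1 SD = {irf.shock_magnitude:.2f}), "
        f"response: {irf.response}"
    )
    return ax
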