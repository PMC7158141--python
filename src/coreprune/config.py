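"""Global numerical tolerances.

All support/"nonzero" decisions throughout the package use ``ZERO_TOL``;
LP feasibility and rank decisions use ``FEASIBILITY_TOL``.  Both can be
overridden per call, but every algorithm reads these defaults so that a
single place controls what "zero flux" means.
"""

#: Absolute tolerance below which a flux value counts as zero.  The core
#: LPs scale certified fluxes to magnitude >= 1, so 1e-6 is far from the
#: signal.
ZERO_TOL = 1e-6

#: Feasibility / rank tolerance for LP residuals and null-space
#: factorizations (relative to the largest singular value).
FEASIBILITY_TOL = 1e-9
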