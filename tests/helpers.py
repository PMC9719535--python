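import numpy as np
import pandas as pd

from lncoop.io import OmicsBundle


def make_bundle(lnc, mrna, cnv, meth, label="TEST") -> OmicsBundle:
    """Assemble an OmicsBundle from plain arrays (features x samples)."""

    def df(arr, prefix):
        arr = np.asarray(arr, dtype=float)
        return pd.DataFrame(
            arr,
            index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )

    return OmicsBundle(
        lncrna_expr=df(lnc, "lnc"),
        mrna_expr=df(mrna, "g"),
        cnv=df(cnv, "g"),
        meth=df(meth, "g"),
        cancer_label=label,
    )
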