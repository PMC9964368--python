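"""mealnir: NIR chemometrics for living mealworm larvae.

PLS1 calibration of fat and fatty-acid content from near-infrared
spectra (1100-2100 nm), with the standard chemometric pretreatments
(MSC, detrend, mean centering, Savitzky-Golay derivatives), RMSECV
latent-variable selection, R2/RMSE/RPD model diagnostics, fatty-acid
class accounting, insect-rearing growth metrics, diet-formulation
arithmetic, and a synthetic spectra generator for end-to-end testing.
"""

from .calibration import (
    ANALYTES,
    CalibrationResults,
    NIRCalibration,
    run_calibration,
)
from .composition import (
    ClassSums,
    FattyAcidProfile,
    class_sums,
    peak_areas_to_percent,
    validate_profile_consistency,
)
from .husbandry import (
    DietFormulation,
    GrowthMetrics,
    GrowthRecord,
    growth_metrics,
    mix_nutrients,
    solve_component_values,
    solve_inclusion,
)
from .metrics import CalibrationReport, r2_fat_correlation, r_squared, rmse, rpd
from .pls import CVResult, PLSModel, cross_validate, fit_pls1, select_n_lv
from .preprocess import (
    FittedPretreatment,
    PretreatmentSpec,
    apply_pipeline,
    detrend,
    mean_center_fit,
    msc_fit_apply,
    msc_transform,
    sg_derivative,
)
from .simulate import (
    BandSpec,
    GroupSpec,
    SyntheticConfig,
    generate_reference,
    generate_spectra,
    make_case_study,
)
from .spectra import (
    ReferenceTable,
    SpectraSet,
    SummaryStats,
    WavelengthGrid,
    average_replicates,
    read_reference_csv,
    read_spectra_csv,
    summarize_reference,
    write_reference_csv,
    write_spectra_csv,
)

__version__ = "0.1.0"
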