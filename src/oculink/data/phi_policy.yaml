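# Default PHI masking policy: DICOM attributes carrying direct identifiers,
# drawn from the standard attribute-confidentiality set (names, birthdates,
# IDs, addresses, phone numbers, institutions). Edit and re-certify for any
# production deployment; linkage-critical UIDs must never be listed here.
#
# Actions: blank (empty value), fixed_literal (replace with `literal`),
# remove_value (value element kept, value set to none).
literal: REMOVED
tags:
  "0010,0010": blank          # PatientName
  "0010,0030": blank          # PatientBirthDate
  "0010,1000": blank          # OtherPatientIDs
  "0010,1001": blank          # OtherPatientNames
  "0010,1040": blank          # PatientAddress
  "0010,2154": blank          # PatientTelephoneNumbers
  "0010,21B0": blank          # AdditionalPatientHistory
  "0008,0050": blank          # AccessionNumber
  "0008,0080": fixed_literal  # InstitutionName
  "0008,0081": blank          # InstitutionAddress
  "0008,0090": blank          # ReferringPhysicianName
  "0008,1010": blank          # StationName
  "0008,1048": blank          # PhysiciansOfRecord
  "0008,1050": blank          # PerformingPhysicianName
  "0008,1070": blank          # OperatorsName
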