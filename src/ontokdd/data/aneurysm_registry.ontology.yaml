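schema_version: 1
name: aneurysm_registry
entities:
  - name: Patient
  - name: Aneurysm
    parent: Patient
    foreign_key: patient_id
hierarchies:
  - name: cerebral_locations
    root:
      id: cerebral_vasculature
      label: Cerebral vasculature
      children:
        - id: anterior_circulation
          label: Anterior circulation
          children:
            - id: AComm
              label: Anterior Communicating
            - id: MCA
              label: Middle Cerebral Artery
            - id: ICA
              label: Internal Carotid Artery
            - id: Pericallosal
              label: Pericallosal Artery
        - id: posterior_circulation
          label: Posterior circulation
          children:
            - id: BasilarTip
              label: Basilar Tip
            - id: PICA
              label: Posterior Inferior Cerebellar Artery
            - id: Vertebral
              label: Vertebral Artery
            - id: PComm
              label: Posterior Communicating
attributes:
  - name: Patient.Sex
    kind: categorical
    categories: [female, male]
    nullable: false
  - name: Patient.Age
    kind: numeric
    unit: years
    range: [18, 90]
  - name: Patient.NumberOfAneurysms
    kind: numeric
    range: [0, 50]
  - name: Aneurysm.Presentation
    kind: categorical
    categories: [Epilepsy, Follow-up, SAH, Coincidental]
  - name: Aneurysm.Location
    kind: hierarchical
    hierarchy: cerebral_locations
  - name: Aneurysm.Width
    kind: numeric
    unit: mm
    range: [0.5, 60]
  - name: Aneurysm.Ruptured
    kind: boolean
    nullable: false
derived:
  - name: Patient.NumberOfAneurysms
    expression: count(Aneurysm)
rules: []
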