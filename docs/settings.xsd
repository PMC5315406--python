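<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the run-settings XML consumed by the `aspasia` CLI.

     A settings document selects a technique, points at the SBML model and
     output directory, declares perturbation ranges, and (for intervention
     runs) the targets to change. Optional elements take the defaults noted
     below; applied defaults are recorded on the parsed Settings object. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:element name="aspasia">
    <xs:complexType>
      <xs:all>
        <xs:element name="technique" type="techniqueType"/>
        <xs:element name="modelPath" type="xs:string"/>
        <xs:element name="outputDir" type="xs:string"/>
        <xs:element name="solver" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="tEnd" type="positiveDouble" default="100"/>
            <xs:attribute name="step" type="positiveDouble" default="0.1"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="lhs" minOccurs="0">
          <xs:complexType>
            <!-- must be >= 2 when technique = LHS -->
            <xs:attribute name="samples" type="xs:positiveInteger" default="2"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="efast" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="curves" type="xs:positiveInteger" default="3"/>
            <!-- must be odd and >= 65 when technique = EFAST -->
            <xs:attribute name="samplesPerCurve" type="xs:positiveInteger" default="65"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="local" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="increments" type="xs:positiveInteger" default="10"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="seed" type="xs:integer" minOccurs="0"/>
        <xs:element name="parameters" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="parameter" maxOccurs="unbounded">
                <xs:complexType>
                  <!-- min < max; min <= baseline <= max when given;
                       baseline required for technique = LOCAL -->
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="kind" type="kindType" default="parameter"/>
                  <xs:attribute name="min" type="xs:double" use="required"/>
                  <xs:attribute name="max" type="xs:double" use="required"/>
                  <xs:attribute name="baseline" type="xs:double"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="interventions" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="intervention" maxOccurs="unbounded">
                <xs:complexType>
                  <!-- SET: magnitude is the new value; SCALE: magnitude (> 0)
                       multiplies the target's final-state value -->
                  <xs:attribute name="target" type="xs:string" use="required"/>
                  <xs:attribute name="kind" type="kindType" default="species_initial"/>
                  <xs:attribute name="mode" type="modeType" default="SET"/>
                  <xs:attribute name="magnitude" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:all>
    </xs:complexType>
  </xs:element>

  <xs:simpleType name="techniqueType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="LOCAL"/>
      <xs:enumeration value="LHS"/>
      <xs:enumeration value="EFAST"/>
      <xs:enumeration value="SNAPSHOT"/>
      <xs:enumeration value="INTERVENTION"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="kindType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="parameter"/>
      <xs:enumeration value="species_initial"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="modeType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="SET"/>
      <xs:enumeration value="SCALE"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="positiveDouble">
    <xs:restriction base="xs:double">
      <xs:minExclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>

</xs:schema>
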