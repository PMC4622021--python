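<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the exported phenotype record database. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">
  <xs:element name="phenotype_db">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="phenotype" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="term" type="xs:string"/>
              <xs:element name="identifier" type="xs:string"/>
              <xs:element name="annotation_date" type="xs:date"/>
              <xs:element name="vocabulary_links">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="concept" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="role" use="required">
                              <xs:simpleType>
                                <xs:restriction base="xs:string">
                                  <xs:enumeration value="quality"/>
                                  <xs:enumeration value="entity"/>
                                </xs:restriction>
                              </xs:simpleType>
                            </xs:attribute>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="disorders">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="disorder" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="support_count" type="xs:nonNegativeInteger" use="required"/>
                            <xs:attribute name="confidence" type="xs:double" use="required"/>
                            <xs:attribute name="p_value" type="xs:double" use="required"/>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="literature">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="occurrence" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="pmid" type="xs:string" use="required"/>
                        <xs:attribute name="sent_index" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="pattern_id" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="df_pmid" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="df" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="surface" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
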